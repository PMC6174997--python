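"""Tabular input/output with strict validation.

Every on-disk format is plain TSV, UTF-8, LF line endings:

* genotype matrix — first column ``marker``, remaining columns one per RIL,
  cells coded ``A``/``B``/``H``/``N`` (see :mod:`namrecomb.codes`);
* genetic map — columns ``marker``, ``chrom``, ``cm`` and optionally ``mb``
  and ``bin``;
* result tables — arbitrary DataFrames written with deterministic column
  order and fixed float precision, accompanied by a ``MANIFEST.tsv`` listing
  every file with its row count.

Heterozygous calls are recoded to missing on load by default: residual
heterozygosity in advanced inbred lines is rare and indistinguishable from
genotyping artefacts at the calling stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import codes


@dataclass
class RILGenotypes:
    """One family's marker x RIL call matrix.

    ``calls`` has shape ``(n_markers, n_rils)`` and int8 entries from
    :mod:`namrecomb.codes`.
    """

    family: str
    common_parent: str
    alt_parent: str
    markers: list[str]
    rils: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker ids")
        if self.calls.shape != (len(self.markers), len(self.rils)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.rils)} RILs"
            )
        bad = ~np.isin(self.calls, [codes.P1, codes.P2, codes.HET, codes.MISSING])
        if bad.any():
            raise ValueError("call matrix contains codes outside {A,B,H,N}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_rils(self) -> int:
        return len(self.rils)

    def recode_het_missing(self) -> "RILGenotypes":
        """Return a copy with every heterozygous call set to missing."""
        calls = self.calls.copy()
        calls[calls == codes.HET] = codes.MISSING
        return replace(self, calls=calls, markers=list(self.markers), rils=list(self.rils))

    def missing_per_ril(self) -> np.ndarray:
        return (self.calls == codes.MISSING).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(codes.decode(self.calls), columns=self.rils)
        df.insert(0, "marker", self.markers)
        return df


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def load_genotypes(
    path: str | os.PathLike,
    family: str = "",
    common_parent: str = "P1",
    alt_parent: str = "P2",
    recode_het: bool = True,
) -> RILGenotypes:
    """Read a genotype matrix TSV.

    The header row gives RIL ids; the first column holds marker ids.  With
    ``recode_het`` (default), ``H`` cells are stored as missing.  Unknown
    codes, duplicate marker ids and ragged rows raise :class:`ParseError`
    naming the line.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        rils = cols[1:]
        ncol = len(cols)
        markers: list[str] = []
        rows: list[list[str]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ParseError(
                    f"{path}:{lineno}: expected {ncol} columns, found {len(parts)}"
                )
            mid = parts[0]
            if mid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate marker id {mid!r}")
            seen.add(mid)
            markers.append(mid)
            rows.append(parts[1:])
    arr = np.array(rows, dtype="U1") if rows else np.empty((0, len(rils)), dtype="U1")
    try:
        calls = codes.encode(arr)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    genos = RILGenotypes(
        family=family or os.path.splitext(os.path.basename(path))[0],
        common_parent=common_parent,
        alt_parent=alt_parent,
        markers=markers,
        rils=rils,
        calls=calls,
    )
    if recode_het:
        genos = genos.recode_het_missing()
    return genos


def write_genotypes(genos: RILGenotypes, path: str | os.PathLike) -> None:
    df = genos.to_frame()
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_map(path: str | os.PathLike, auto_sort: bool = False) -> pd.DataFrame:
    """Read a genetic-map TSV with columns ``marker``, ``chrom``, ``cm``
    (optionally ``mb``, ``bin``).

    Positions must be sorted non-decreasing within each chromosome unless
    ``auto_sort`` is set.  Non-numeric positions raise :class:`ParseError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    for col in ("marker", "chrom", "cm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    try:
        df["cm"] = df["cm"].astype(float)
    except (TypeError, ValueError):
        raise ParseError(f"{path}: non-numeric cm column") from None
    if df["marker"].duplicated().any():
        dup = df["marker"][df["marker"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate marker id {dup!r}")
    if auto_sort:
        df = df.sort_values(["chrom", "cm"], kind="stable").reset_index(drop=True)
    else:
        for chrom, sub in df.groupby("chrom", sort=False):
            if np.any(np.diff(sub["cm"].to_numpy()) < 0):
                raise ParseError(
                    f"{path}: positions on {chrom} not sorted (pass auto_sort=True)"
                )
    return df.reset_index(drop=True)


def write_map(gmap: pd.DataFrame, path: str | os.PathLike) -> None:
    gmap.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def check_markers_mapped(genos: RILGenotypes, gmap: pd.DataFrame) -> None:
    """Raise ``ValueError`` listing genotype markers absent from the map."""
    known = set(gmap["marker"])
    missing = [m for m in genos.markers if m not in known]
    if missing:
        shown = ", ".join(missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(f"markers absent from map: {shown}{more}")


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | os.PathLike) -> list[str]:
    """Write each table as ``<name>.tsv`` plus a ``MANIFEST.tsv``.

    Column order is preserved as given, floats use fixed ``%.6g`` precision,
    and rewriting identical inputs produces byte-identical files.  Returns
    the list of files written.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    manifest_rows = []
    for name in sorted(tables):
        df = tables[name]
        fname = f"{name}.tsv"
        df.to_csv(
            os.path.join(out_dir, fname),
            sep="\t",
            index=False,
            lineterminator="\n",
            float_format="%.6g",
        )
        written.append(fname)
        manifest_rows.append({"file": fname, "n_rows": len(df), "n_cols": df.shape[1]})
    manifest = pd.DataFrame(manifest_rows, columns=["file", "n_rows", "n_cols"])
    manifest.to_csv(
        os.path.join(out_dir, "MANIFEST.tsv"), sep="\t", index=False, lineterminator="\n"
    )
    written.append("MANIFEST.tsv")
    return written
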