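"""Crossover calling and recombination phenotypes.

A crossover (CO) is called as a change in the parental genotype phase along
a map-ordered chromosome.  The rule requires ``k`` consecutive supporting
markers per phase run (default ``k = 2``): missing calls are skipped, calls
are compressed into maximal same-phase runs, runs shorter than ``k`` —
including terminal runs — are discarded as probable genotyping or map-order
errors, adjacent surviving runs of equal phase are merged, and one CO is
emitted per remaining phase transition, localized between the flanking
informative markers of the adjoining runs.  The single-marker rule
(``k = 1``) counts every phase switch; for any input the two-marker count is
bounded above by the single-marker count.

Phenotypes: TCO is the total CO count per RIL; pCO and dCO split it by the
arm partition (pericentromeric inner 2/3 of each arm vs distal outer 1/3),
classifying each CO by its breakpoint position (interval midpoint).  A
breakpoint exactly on the partition boundary counts as pericentromeric.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import codes
from .genome import ArmPartition, GenomeModel
from .io import RILGenotypes

logger = logging.getLogger(__name__)

CO_COLUMNS = [
    "ril", "chrom", "left_marker", "right_marker",
    "left_cm", "right_cm", "pos_cm", "phase_from", "phase_to",
]


def _marker_order(genos: RILGenotypes, gmap: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per chromosome: (row indices into genos.calls, marker ids, cM), map-ordered."""
    gm = gmap.set_index("marker")
    missing = [m for m in genos.markers if m not in gm.index]
    if missing:
        raise ValueError(f"markers absent from map: {missing[:5]}")
    chroms = gm.loc[genos.markers, "chrom"].to_numpy()
    cms = gm.loc[genos.markers, "cm"].to_numpy(dtype=float)
    out = {}
    marker_arr = np.asarray(genos.markers)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        order = idx[np.argsort(cms[idx], kind="stable")]
        out[str(chrom)] = (order, marker_arr[order], cms[order])
    return out


def call_crossovers(
    genos: RILGenotypes,
    gmap: pd.DataFrame,
    k: int = 2,
) -> pd.DataFrame:
    """Call crossovers for every RIL with the ``k``-consecutive-marker rule.

    Heterozygous calls are treated as missing (recode beforehand or at
    load).  Returns a DataFrame with columns :data:`CO_COLUMNS`; the
    breakpoint ``pos_cm`` is the genetic midpoint of the flanking interval.
    A chromosome with fewer than ``k`` informative markers for a RIL yields
    no calls (logged once per chromosome).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_chrom = _marker_order(genos, gmap)
    rows: list[tuple] = []
    for chrom, (ridx, mids, cms) in by_chrom.items():
        sub = genos.calls[ridx, :]
        informative = (sub == codes.P1) | (sub == codes.P2)
        n_short = 0
        for j, ril in enumerate(genos.rils):
            sel = informative[:, j]
            if sel.sum() < k:
                n_short += 1
                continue
            phases = sub[sel, j]  # 0 = P1, 1 = P2
            pos = cms[sel]
            ids = mids[sel]
            # maximal same-phase runs
            change = np.flatnonzero(np.diff(phases) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(phases)]))
            lens = ends - starts
            keep = lens >= k
            if keep.sum() < 2:
                continue
            ks, ke = starts[keep], ends[keep]
            kph = phases[ks]
            # merge adjacent equal phases, then emit COs at transitions
            prev_end = ke[0] - 1
            prev_phase = kph[0]
            for s, e, ph in zip(ks[1:], ke[1:], kph[1:]):
                if ph == prev_phase:
                    prev_end = e - 1
                    continue
                li, ri = prev_end, s
                rows.append(
                    (
                        ril, chrom, ids[li], ids[ri],
                        float(pos[li]), float(pos[ri]),
                        float((pos[li] + pos[ri]) / 2.0),
                        int(prev_phase), int(ph),
                    )
                )
                prev_end = e - 1
                prev_phase = ph
        if n_short:
            logger.warning(
                "%s: %d RILs with fewer than %d informative markers; no calls",
                chrom, n_short, k,
            )
    return pd.DataFrame(rows, columns=CO_COLUMNS)


def collapse_redundant_markers(
    genos: RILGenotypes,
    min_overlap: int = 15,
) -> tuple[pd.Series, list[str]]:
    """Group markers carrying identical genotype information into bins.

    Two markers land in the same bin when they agree at every RIL where both
    are non-missing and share at least ``min_overlap`` informative RILs;
    the relation is closed transitively.  The delegate of each bin is the
    member with the fewest missing calls (ties broken by map order, i.e.
    input order).  Returns ``(bin_id per marker, delegates)``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    m = genos.n_markers
    x = np.zeros((m, genos.n_rils), dtype=np.float32)
    x[genos.calls == codes.P1] = 1.0
    x[genos.calls == codes.P2] = -1.0
    absx = np.abs(x)
    agree_minus_disagree = x @ x.T
    shared = absx @ absx.T
    compatible = (agree_minus_disagree >= shared - 0.5) & (shared >= min_overlap)

    parent = np.arange(m)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    ii, jj = np.nonzero(np.triu(compatible, 1))
    for a, b in zip(ii, jj):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(m)])
    missing = (genos.calls == codes.MISSING).sum(axis=1)
    bin_ids = pd.Series(
        [f"bin{r:05d}" for r in roots], index=genos.markers, name="bin"
    )
    delegates = []
    for r in np.unique(roots):
        members = np.flatnonzero(roots == r)
        best = members[np.argmin(missing[members], )]
        delegates.append(genos.markers[int(best)])
    return bin_ids, delegates


def summarize_phenotypes(
    cos: pd.DataFrame,
    partition: ArmPartition,
    genos: RILGenotypes | None = None,
    missing_threshold: float = 0.10,
) -> pd.DataFrame:
    """Build the per-RIL phenotype table from called crossovers.

    Columns: ``tco``, ``pco``, ``dco``, one ``co_<chrom>`` per chromosome,
    ``n_missing`` and boolean ``excluded`` (RILs whose missing-call count
    exceeds ``missing_threshold`` x marker count; requires ``genos``).
    ``tco == pco + dco == sum of per-chromosome counts`` by construction.
    """
    chroms = list(partition.boundaries)
    for chrom in cos["chrom"].unique() if len(cos) else []:
        if chrom not in partition.boundaries:
            raise ValueError(f"partition does not cover chromosome {chrom!r}")
    rils = list(genos.rils) if genos is not None else sorted(cos["ril"].unique())
    out = pd.DataFrame(index=pd.Index(rils, name="ril"))
    if len(cos):
        lo = np.array([partition.boundaries[c][0] for c in cos["chrom"]])
        hi = np.array([partition.boundaries[c][2] for c in cos["chrom"]])
        pos = cos["pos_cm"].to_numpy(dtype=float)
        bad = (pos < 0) | (pos > np.array([partition.lengths[c] for c in cos["chrom"]]))
        if bad.any():
            raise ValueError("breakpoint outside chromosome bounds")
        distal = (pos < lo) | (pos > hi)
        tagged = cos.assign(_distal=distal)
        per_chrom = tagged.pivot_table(index="ril", columns="chrom", values="pos_cm", aggfunc="size")
        dcount = tagged[tagged["_distal"]].groupby("ril").size()
        pcount = tagged[~tagged["_distal"]].groupby("ril").size()
    else:
        per_chrom = pd.DataFrame(index=out.index)
        dcount = pd.Series(dtype=int)
        pcount = pd.Series(dtype=int)
    for c in chroms:
        col = per_chrom[c] if c in per_chrom.columns else pd.Series(dtype=float)
        out[f"co_{c}"] = col.reindex(out.index).fillna(0).astype(int)
    out["pco"] = pcount.reindex(out.index).fillna(0).astype(int)
    out["dco"] = dcount.reindex(out.index).fillna(0).astype(int)
    out["tco"] = out["pco"] + out["dco"]
    if genos is not None:
        out["n_missing"] = genos.missing_per_ril()
        out["excluded"] = out["n_missing"] > missing_threshold * genos.n_markers
    else:
        out["n_missing"] = 0
        out["excluded"] = False
    return out


def exclude_regions(
    cos: pd.DataFrame,
    exclude: Sequence["str | tuple"],
    partition: ArmPartition,
    genos: RILGenotypes | None = None,
    missing_threshold: float = 0.10,
) -> pd.DataFrame:
    """Recompute phenotypes after dropping crossovers in excluded regions.

    ``exclude`` entries are either a chromosome name (drop the whole
    chromosome), ``(chrom, "peri")`` / ``(chrom, "distal")`` (drop one arm
    region), or ``(chrom, (start, end))`` for an explicit half-open cM
    window.  An empty list reproduces the original table.
    """
    keep = np.ones(len(cos), dtype=bool)
    for item in exclude:
        if isinstance(item, str):
            chrom, region = item, "all"
        else:
            chrom, region = item
        if chrom not in partition.boundaries:
            raise ValueError(f"unknown chromosome {chrom!r}")
        on = cos["chrom"].to_numpy() == chrom
        if isinstance(region, str) and region == "all":
            keep &= ~on
        elif isinstance(region, str):
            pos = cos["pos_cm"].to_numpy(dtype=float)
            lo, _c, hi = partition.boundaries[chrom]
            if region in ("peri", "pericentromeric"):
                # pericentromeric owns its boundaries (tie rule)
                inside = (pos >= lo) & (pos <= hi)
            elif region == "distal":
                inside = (pos < lo) | (pos > hi)
            else:
                raise ValueError(f"unknown region {region!r}")
            keep &= ~(on & inside)
        else:
            s, e = region
            pos = cos["pos_cm"].to_numpy(dtype=float)
            keep &= ~(on & (pos >= s) & (pos < e))
    return summarize_phenotypes(cos[keep], partition, genos=genos,
                                missing_threshold=missing_threshold)


def breakpoint_distribution(
    cos: pd.DataFrame,
    model: GenomeModel,
    n_bins: int = 20,
    partition: ArmPartition | None = None,
) -> tuple[np.ndarray, float]:
    """Histogram of breakpoints on the scaled [0, 1] chromosome coordinate.

    Every breakpoint position is divided by its chromosome length and all
    chromosomes are pooled.  Returns ``(counts, fraction_distal)`` where the
    histogram sums to the total CO count and ``fraction_distal`` is the share
    of COs falling in the distal thirds of the arms.
    """
    if partition is None:
        partition = ArmPartition.from_model(model)
    if len(cos) == 0:
        return np.zeros(n_bins, dtype=int), float("nan")
    lengths = np.array([model.chrom(c).length_cm for c in cos["chrom"]])
    scaled = cos["pos_cm"].to_numpy(dtype=float) / lengths
    hist, _ = np.histogram(scaled, bins=n_bins, range=(0.0, 1.0))
    lo = np.array([partition.boundaries[c][0] for c in cos["chrom"]])
    hi = np.array([partition.boundaries[c][2] for c in cos["chrom"]])
    pos = cos["pos_cm"].to_numpy(dtype=float)
    frac_distal = float(np.mean((pos < lo) | (pos > hi)))
    return hist, frac_distal


def map_summary(gmap: pd.DataFrame, model: GenomeModel | None = None) -> pd.DataFrame:
    """Per-chromosome (plus per-genome-class and total) map summaries.

    Length is last minus first marker position; cM/Mb is reported when
    physical lengths are available on the model, otherwise left missing.
    """
    rows = []
    for chrom, sub in gmap.groupby("chrom", sort=False):
        cm = sub["cm"].to_numpy(dtype=float)
        length = float(cm.max() - cm.min())
        mb = None
        gclass = ""
        if model is not None:
            try:
                spec = model.chrom(str(chrom))
                mb = spec.physical_mb
                gclass = spec.genome_class
            except KeyError:
                pass
        rows.append(
            {
                "scope": "chrom",
                "name": str(chrom),
                "genome_class": gclass,
                "n_markers": len(sub),
                "length_cm": length,
                "physical_mb": mb,
                "cm_per_mb": None if mb in (None, 0) else length / mb,
            }
        )
    df = pd.DataFrame(rows)
    groups = [df]
    if model is not None and len(df):
        agg_rows = []
        for gclass, sub in df.groupby("genome_class"):
            mb = sub["physical_mb"].sum() if sub["physical_mb"].notna().all() else None
            L = sub["length_cm"].sum()
            agg_rows.append(
                {
                    "scope": "genome",
                    "name": str(gclass),
                    "genome_class": str(gclass),
                    "n_markers": int(sub["n_markers"].sum()),
                    "length_cm": float(L),
                    "physical_mb": mb,
                    "cm_per_mb": None if mb in (None, 0) else L / mb,
                }
            )
        mb = df["physical_mb"].sum() if df["physical_mb"].notna().all() else None
        L = df["length_cm"].sum()
        agg_rows.append(
            {
                "scope": "total", "name": "all", "genome_class": "",
                "n_markers": int(df["n_markers"].sum()), "length_cm": float(L),
                "physical_mb": mb,
                "cm_per_mb": None if mb in (None, 0) else L / mb,
            }
        )
        groups.append(pd.DataFrame(agg_rows))
    return pd.concat(groups, ignore_index=True)


def estimate_map_length(
    genos: RILGenotypes,
    gmap: pd.DataFrame,
    marker_subset: Sequence[str] | None = None,
) -> float:
    """Re-estimate total map length (cM) from RIL genotypes.

    For each adjacent marker pair the observed RIL recombinant fraction
    ``R`` (share of RILs with discordant homozygous calls) is converted to
    the meiotic fraction ``r = R / (2 - 2R)`` (inverting the RIL expansion
    ``R = 2r / (1 + 2r)``) and then to Haldane map distance
    ``d = -50 ln(1 - 2r)``; distances are summed.
    """
    by_chrom = _marker_order(genos, gmap)
    subset = None if marker_subset is None else set(marker_subset)
    total = 0.0
    for chrom, (ridx, mids, cms) in by_chrom.items():
        if subset is not None:
            keep = np.array([m in subset for m in mids])
            ridx = ridx[keep]
        if len(ridx) < 2:
            continue
        sub = genos.calls[ridx, :]
        hom = (sub == codes.P1) | (sub == codes.P2)
        a = sub[:-1, :]
        b = sub[1:, :]
        both = hom[:-1, :] & hom[1:, :]
        diff = (a != b) & both
        n = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            big_r = np.where(n > 0, diff.sum(axis=1) / np.maximum(n, 1), 0.0)
        big_r = np.clip(big_r, 0.0, 0.4999)
        r = big_r / (2.0 - 2.0 * big_r)
        d = -50.0 * np.log(1.0 - 2.0 * np.clip(r, 0.0, 0.4999))
        total += float(d.sum())
    return total


def thinning_experiment(
    genos: RILGenotypes,
    gmap: pd.DataFrame,
    target_marker_count: int,
    n_reps: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Re-estimate the map length from random marker subsets.

    Each replicate samples ``target_marker_count`` markers without
    replacement and re-estimates the summed map length; heavy thinning
    biases the estimate downward because double crossovers between retained
    markers go undetected.  Returns one row per replicate plus the mean and
    SD as attributes ``.attrs['mean_cm']`` / ``.attrs['sd_cm']``.
    """
    if target_marker_count > genos.n_markers:
        raise ValueError("target_marker_count exceeds available markers")
    rng = np.random.default_rng(seed)
    markers = np.asarray(genos.markers)
    rows = []
    for rep in range(n_reps):
        chosen = rng.choice(markers, size=target_marker_count, replace=False)
        rows.append(
            {"rep": rep, "length_cm": estimate_map_length(genos, gmap, chosen)}
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_cm"] = float(df["length_cm"].mean())
    df.attrs["sd_cm"] = float(df["length_cm"].std(ddof=1)) if n_reps > 1 else 0.0
    return df
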