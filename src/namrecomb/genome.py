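"""Genome model: chromosomes, genetic maps, and the arm partition.

Coordinates are genetic (cM), 0-based floats; intervals are half-open
``[start, end)``.  A chromosome is described by its genetic length, the
genetic position of the centromere, an optional physical length (Mb), and a
genome-class label (for an allopolyploid, the subgenome, e.g. ``"A"``,
``"B"``, ``"D"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome of the genome model."""

    name: str
    length_cm: float
    centromere_cm: float
    genome_class: str = "A"
    physical_mb: float | None = None

    def __post_init__(self) -> None:
        if self.length_cm <= 0:
            raise ValueError(f"{self.name}: chromosome length must be positive")
        if not 0 <= self.centromere_cm <= self.length_cm:
            raise ValueError(
                f"{self.name}: centromere at {self.centromere_cm} cM outside "
                f"[0, {self.length_cm}] cM"
            )
        if self.physical_mb is not None and self.physical_mb <= 0:
            raise ValueError(f"{self.name}: physical length must be positive")

    @property
    def cm_per_mb(self) -> float | None:
        if self.physical_mb is None:
            return None
        return self.length_cm / self.physical_mb


@dataclass
class GenomeModel:
    """Ordered chromosomes plus per-chromosome ordered marker positions.

    ``markers`` maps chromosome name to a strictly sorted float array of
    marker positions (cM).  Each chromosome carries at least two markers.
    """

    chromosomes: list[ChromosomeSpec]
    markers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for c in self.chromosomes:
            pos = np.asarray(self.markers.get(c.name, ()), dtype=float)
            if pos.size < 2:
                raise ValueError(f"{c.name}: need at least 2 markers")
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"{c.name}: marker positions must be sorted")
            if pos[0] < 0 or pos[-1] > c.length_cm:
                raise ValueError(f"{c.name}: markers outside chromosome bounds")
            self.markers[c.name] = pos

    def chrom(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length_cm(self) -> float:
        return float(sum(c.length_cm for c in self.chromosomes))

    @property
    def total_length_morgan(self) -> float:
        return self.total_length_cm / 100.0

    @property
    def n_markers(self) -> int:
        return int(sum(len(self.markers[c.name]) for c in self.chromosomes))

    def marker_ids(self, chrom: str) -> list[str]:
        return [f"{chrom}_m{i:04d}" for i in range(len(self.markers[chrom]))]

    def marker_table(self) -> pd.DataFrame:
        """Genetic-map table of all model markers (marker, chrom, cm[, mb])."""
        rows = []
        for c in self.chromosomes:
            pos = self.markers[c.name]
            ids = self.marker_ids(c.name)
            ratio = None if c.physical_mb is None else c.physical_mb / c.length_cm
            for mid, p in zip(ids, pos):
                rows.append(
                    {
                        "marker": mid,
                        "chrom": c.name,
                        "cm": float(p),
                        "mb": None if ratio is None else float(p) * ratio,
                    }
                )
        df = pd.DataFrame(rows)
        if df["mb"].isna().all():
            df = df.drop(columns=["mb"])
        return df


def build_genome_model(config: Mapping | Sequence[Mapping]) -> GenomeModel:
    """Build a :class:`GenomeModel` from a plain configuration.

    ``config`` is either a mapping with a ``"chromosomes"`` key or directly a
    sequence of per-chromosome mappings with keys ``name``, ``length_cm``,
    ``centromere_cm`` (default: midpoint), ``genome_class`` (default ``"A"``),
    ``physical_mb`` (optional) and either ``n_markers`` (markers placed
    uniformly from 0 to the chromosome end) or ``marker_cm`` (explicit
    positions).

    Raises ``ValueError`` for non-positive lengths, a centromere outside the
    chromosome, or fewer than two markers.
    """
    if isinstance(config, Mapping):
        chrom_cfgs = config["chromosomes"]
    else:
        chrom_cfgs = config
    if not chrom_cfgs:
        raise ValueError("config names no chromosomes")
    chroms: list[ChromosomeSpec] = []
    markers: dict[str, np.ndarray] = {}
    for cfg in chrom_cfgs:
        spec = ChromosomeSpec(
            name=str(cfg["name"]),
            length_cm=float(cfg["length_cm"]),
            centromere_cm=float(cfg.get("centromere_cm", float(cfg["length_cm"]) / 2)),
            genome_class=str(cfg.get("genome_class", "A")),
            physical_mb=(None if cfg.get("physical_mb") is None else float(cfg["physical_mb"])),
        )
        if "marker_cm" in cfg:
            pos = np.asarray(cfg["marker_cm"], dtype=float)
        else:
            n = int(cfg.get("n_markers", 0))
            if n < 2:
                raise ValueError(f"{spec.name}: n_markers must be >= 2")
            pos = np.linspace(0.0, spec.length_cm, n)
        chroms.append(spec)
        markers[spec.name] = pos
    return GenomeModel(chromosomes=chroms, markers=markers)


def uniform_genome(
    n_chrom: int,
    length_cm: float,
    n_markers: int,
    centromere_cm: float | None = None,
    genome_class: str = "A",
    physical_mb: float | None = None,
    prefix: str = "chr",
) -> GenomeModel:
    """Convenience builder: ``n_chrom`` identical chromosomes with uniformly
    spaced markers."""
    return build_genome_model(
        [
            {
                "name": f"{prefix}{i + 1}",
                "length_cm": length_cm,
                "centromere_cm": length_cm / 2 if centromere_cm is None else centromere_cm,
                "genome_class": genome_class,
                "physical_mb": physical_mb,
                "n_markers": n_markers,
            }
            for i in range(n_chrom)
        ]
    )


@dataclass
class ArmPartition:
    """Distal / pericentromeric partition of every chromosome arm.

    Each arm is split at a fixed fraction measured from the telomere: the
    outer ``distal_fraction`` of the arm is "distal", the inner remainder
    (adjacent to the centromere) is "pericentromeric".  With the default
    fraction of 1/3, a position is distal when it lies in the outer third of
    its arm.  A breakpoint falling exactly on a boundary is assigned to the
    pericentromeric class.
    """

    boundaries: dict[str, tuple[float, float, float]]  # chrom -> (lo, centromere, hi)
    lengths: dict[str, float]
    distal_fraction: float = 1.0 / 3.0

    @classmethod
    def from_model(cls, model: GenomeModel, distal_fraction: float = 1.0 / 3.0) -> "ArmPartition":
        if not 0 < distal_fraction < 1:
            raise ValueError("distal_fraction must be in (0, 1)")
        bounds = {}
        lengths = {}
        for c in model.chromosomes:
            lo = c.centromere_cm * distal_fraction
            hi = c.length_cm - (c.length_cm - c.centromere_cm) * distal_fraction
            bounds[c.name] = (lo, c.centromere_cm, hi)
            lengths[c.name] = c.length_cm
        return cls(boundaries=bounds, lengths=lengths, distal_fraction=distal_fraction)

    def is_distal(self, chrom: str, pos_cm: "float | np.ndarray") -> "bool | np.ndarray":
        """Classify positions; boundary ties are pericentromeric."""
        lo, _c, hi = self.boundaries[chrom]
        pos = np.asarray(pos_cm, dtype=float)
        out = (pos < lo) | (pos > hi)
        if np.isscalar(pos_cm):
            return bool(out)
        return out

    def region_bounds(self, chrom: str, region: str) -> list[tuple[float, float]]:
        """Half-open cM intervals making up ``region`` ('distal'|'peri') of a
        chromosome; used to target intensity modifiers and region exclusion."""
        lo, _c, hi = self.boundaries[chrom]
        if region in ("peri", "pericentromeric"):
            return [(lo, hi)]
        if region == "distal":
            return [(0.0, lo), (hi, self.lengths[chrom])]
        raise ValueError(f"unknown region {region!r}")
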