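"""Deleterious load, founder LD, and IBD contrasts against recombination.

The genome is cut into fixed genetic bins per chromosome; crossover
breakpoints are tallied per bin.  High-recombining bins are those in the
distal 10% of either chromosome end (on the scaled 0–1 coordinate) — in
distally recombining genomes these capture the large majority of crossover
events.  Contrasts:

* load contrast — one-sided Fisher's exact test for a *reduction* in the
  proportion of deleterious SNPs in the high-recombining class;
* LD vs recombination — mean pairwise r² among founder alleles per bin,
  correlated (Pearson) with the bin's breakpoint count;
* IBD contrast — Mann–Whitney U comparing per-region crossover counts
  between regions identical-by-descent with the common parent and the rest.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel

logger = logging.getLogger(__name__)


def make_bins(model: GenomeModel, cos: pd.DataFrame, n_bins_per_chrom: int = 20) -> pd.DataFrame:
    """Equal-width genetic bins per chromosome with breakpoint counts.

    Returns columns ``chrom, bin, start_cm, end_cm, mid_scaled, n_co``.
    """
    rows = []
    for c in model.chromosomes:
        edges = np.linspace(0.0, c.length_cm, n_bins_per_chrom + 1)
        pos = cos.loc[cos["chrom"] == c.name, "pos_cm"].to_numpy(dtype=float) if len(cos) else np.array([])
        counts, _ = np.histogram(pos, bins=edges)
        for b in range(n_bins_per_chrom):
            rows.append(
                {
                    "chrom": c.name,
                    "bin": b,
                    "start_cm": float(edges[b]),
                    "end_cm": float(edges[b + 1]),
                    "mid_scaled": float((edges[b] + edges[b + 1]) / 2.0 / c.length_cm),
                    "n_co": int(counts[b]),
                }
            )
    return pd.DataFrame(rows)


def define_high_recomb_regions(bins: pd.DataFrame, distal_pct: float = 10.0) -> tuple[pd.DataFrame, float]:
    """Flag bins in the distal ``distal_pct`` % of either chromosome end.

    Returns the table with a boolean ``high_recomb`` column plus the
    fraction of all crossover events captured by the flagged bins.
    """
    if not 0 < distal_pct < 50:
        raise ValueError("distal_pct must be in (0, 50)")
    f = distal_pct / 100.0
    out = bins.copy()
    out["high_recomb"] = (out["mid_scaled"] <= f) | (out["mid_scaled"] >= 1.0 - f)
    total = out["n_co"].sum()
    captured = out.loc[out["high_recomb"], "n_co"].sum()
    frac = float(captured / total) if total else float("nan")
    return out, frac


def load_contrast(bins: pd.DataFrame) -> dict:
    """One-sided Fisher test for reduced deleterious load in high bins.

    ``bins`` needs ``high_recomb``, ``deleterious`` and ``non_deleterious``
    count columns.  The p-value is the hypergeometric tail probability that
    the high-recombining class holds as few or fewer deleterious SNPs given
    the margins.
    """
    for col in ("high_recomb", "deleterious", "non_deleterious"):
        if col not in bins.columns:
            raise ValueError(f"missing column {col!r}")
    hi = bins[bins["high_recomb"]]
    lo = bins[~bins["high_recomb"]]
    d_hi, n_hi = int(hi["deleterious"].sum()), int(hi["non_deleterious"].sum())
    d_lo, n_lo = int(lo["deleterious"].sum()), int(lo["non_deleterious"].sum())
    if d_hi + n_hi == 0 or d_lo + n_lo == 0:
        raise ValueError("empty recombination class")
    table = np.array([[d_hi, n_hi], [d_lo, n_lo]])
    _odds, p = stats.fisher_exact(table, alternative="less")
    return {
        "prop_high": d_hi / (d_hi + n_hi),
        "prop_rest": d_lo / (d_lo + n_lo),
        "table": table,
        "p": float(p),
    }


def annotation_to_bin_counts(bins: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Attach per-bin deleterious / non-deleterious counts from a SNP
    annotation table (columns ``chrom``, ``bin``, ``deleterious``)."""
    grp = annotation.groupby(["chrom", "bin"])["deleterious"]
    dele = grp.sum()
    tot = grp.size()
    out = bins.copy()
    key = list(zip(out["chrom"], out["bin"]))
    out["deleterious"] = [int(dele.get(k, 0)) for k in key]
    out["non_deleterious"] = [int(tot.get(k, 0) - dele.get(k, 0)) for k in key]
    return out


def ld_per_bin(
    founder_alleles: np.ndarray,
    marker_bins: pd.DataFrame,
) -> pd.DataFrame:
    """Mean pairwise r² among founder alleles for every bin.

    ``founder_alleles`` is (n_founders, n_markers) 0/1; ``marker_bins`` maps
    each marker column to a ``(chrom, bin)``.  r² is the squared Pearson
    correlation of allele indicators across founders; monomorphic markers
    are excluded and bins with fewer than two usable markers are dropped
    (logged).
    """
    x = np.asarray(founder_alleles, dtype=float)
    rows = []
    dropped = 0
    for (chrom, b), sub in marker_bins.groupby(["chrom", "bin"], sort=True):
        cols = sub.index.to_numpy()
        block = x[:, cols]
        poly = block.std(axis=0) > 0
        block = block[:, poly]
        if block.shape[1] < 2:
            dropped += 1
            continue
        corr = np.corrcoef(block, rowvar=False)
        iu = np.triu_indices(corr.shape[0], k=1)
        rows.append({"chrom": chrom, "bin": b, "mean_r2": float(np.mean(corr[iu] ** 2)),
                     "n_markers": int(block.shape[1])})
    if dropped:
        logger.info("ld_per_bin: %d bins dropped (<2 polymorphic markers)", dropped)
    return pd.DataFrame(rows, columns=["chrom", "bin", "mean_r2", "n_markers"])


def ld_recomb_correlation(bins: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between per-bin mean r² and breakpoint count.

    ``bins`` needs ``mean_r2`` and ``n_co`` columns (bins with undefined r²
    already dropped).  Fewer than 3 usable bins or zero variance in either
    variable is an error.
    """
    sub = bins.dropna(subset=["mean_r2"])
    if len(sub) < 3:
        raise ValueError("need at least 3 bins with defined r2")
    x = sub["mean_r2"].to_numpy(dtype=float)
    y = sub["n_co"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ibd_co_contrast(
    ibd_tracts: pd.DataFrame,
    cos: pd.DataFrame,
    regions: pd.DataFrame,
    family_founders: dict[str, str] | None = None,
    min_coverage: float = 0.5,
    alternative: str = "greater",
) -> dict:
    """Mann–Whitney U contrast of crossover counts in IBD vs non-IBD regions.

    ``regions`` has columns ``chrom, start_cm, end_cm`` (half-open).  A
    (family, region) observation is the number of that family's crossovers
    inside the region; it belongs to the IBD sample when at least
    ``min_coverage`` of the region's span is covered by IBD tracts of the
    family's founder.  ``family_founders`` maps each family id in ``cos``
    (column ``family``; absent column means a single unnamed family) to its
    founder name in ``ibd_tracts``.  The U statistic is reported for the
    IBD sample (brute-force pair-count orientation: U = pairs where an IBD
    count exceeds a non-IBD count, ties counting half); the default
    one-sided alternative tests for *more* crossovers in IBD regions.
    """
    if "family" not in cos.columns:
        cos = cos.assign(family="fam")
        if family_founders is None:
            founders = ibd_tracts["founder"].unique()
            family_founders = {"fam": founders[0] if len(founders) else ""}
    ibd_counts: list[int] = []
    non_counts: list[int] = []
    for fam, sub in cos.groupby("family"):
        founder = (family_founders or {}).get(fam, "")
        tracts = ibd_tracts[ibd_tracts["founder"] == founder]
        for _, reg in regions.iterrows():
            span = reg["end_cm"] - reg["start_cm"]
            t = tracts[tracts["chrom"] == reg["chrom"]]
            cov = 0.0
            for _, tr in t.iterrows():
                s = max(tr["start_cm"], reg["start_cm"])
                e = min(tr["end_cm"], reg["end_cm"])
                cov += max(0.0, e - s)
            on = sub[
                (sub["chrom"] == reg["chrom"])
                & (sub["pos_cm"] >= reg["start_cm"])
                & (sub["pos_cm"] < reg["end_cm"])
            ]
            (ibd_counts if span > 0 and cov / span >= min_coverage else non_counts).append(len(on))
    if not ibd_counts or not non_counts:
        raise ValueError("one of the IBD / non-IBD samples is empty")
    u, p = stats.mannwhitneyu(ibd_counts, non_counts, alternative=alternative)
    return {
        "u": float(u),
        "p": float(p),
        "n_ibd": len(ibd_counts),
        "n_non": len(non_counts),
        "mean_ibd": float(np.mean(ibd_counts)),
        "mean_non": float(np.mean(non_counts)),
    }
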