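"""Joint QTL mapping across NAM families.

Families sharing a common parent are analysed together on a shared marker
coordinate system.  Two procedures are provided:

* :func:`joint_stepwise` — forward stepwise regression in which every locus
  enters as a block of family-nested dosage effects on top of per-family
  intercepts (the common-parent allele is the reference in every family, so
  effects are directly comparable across families);
* :func:`joint_scan` — a family-stratified interval scan: at each grid
  position the family-intercept-only model is compared with the model adding
  family-nested dosage terms, giving a joint LOD profile with thresholds
  from within-family phenotype permutations.

Because all model columns (intercepts and nested dosages) have support in a
single family, the joint least-squares problem separates by family, which
the implementation exploits for speed.

Missing marker genotypes are imputed as flanking-marker expected dosages
(see :func:`namrecomb.qtl_scan.dosage_matrix`).  The effect-sign convention
matches the single-family scan: positive means the common-parent allele
increases the trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import RILGenotypes
from .qtl_scan import QTLResult, ScanProfile, dosage_matrix, find_qtl, make_grid

logger = logging.getLogger(__name__)


@dataclass
class JointModel:
    """Result of the nested-family stepwise regression."""

    loci: list[str]  # marker ids in entry order
    effects: pd.DataFrame  # marker, family, effect (P1-positive), entry_p
    family_means: pd.DataFrame  # family, intercept
    r2: float
    r2_path: list[float]
    p_enter: float
    trait: str = "tco"


def _family_blocks(
    families: list[tuple[RILGenotypes, np.ndarray]],
    gmap: pd.DataFrame,
    loci: pd.DataFrame,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per family: phenotype vector and (n_loci, n_rils) dosage matrix."""
    ys, ds = [], []
    for genos, y in families:
        y = np.asarray(y, dtype=float)
        if len(y) != genos.n_rils:
            raise ValueError(f"{genos.family}: phenotype/RIL mismatch")
        ys.append(y)
        ds.append(dosage_matrix(genos, gmap, loci))
    return ys, ds


def joint_stepwise(
    families: list[tuple[RILGenotypes, np.ndarray]],
    gmap: pd.DataFrame,
    p_enter: float = 1e-4,
    candidate_step_cm: float = 2.0,
    max_loci: int = 25,
    trait: str = "tco",
) -> JointModel:
    """Forward stepwise regression with family-nested marker effects.

    Candidate loci are a grid over the shared map (``candidate_step_cm``).
    At each step the locus whose nested-dosage block gives the smallest
    F-test p-value enters if ``p < p_enter``; selection stops otherwise.
    The model R² is non-decreasing along the forward path.
    """
    families = [(g, y) for g, y in families if len(y) > 0]
    if not families:
        raise ValueError("no families with usable RILs")
    nf = len(families)
    grid = make_grid(gmap, candidate_step_cm)
    ys, ds = _family_blocks(families, gmap, grid)
    n_tot = sum(len(y) for y in ys)
    tss = sum(float(((y - y.mean()) ** 2).sum()) for y in ys)

    # per-family residual state (model separates by family)
    res_y = [y - y.mean() for y in ys]
    res_d = [d - d.mean(axis=1, keepdims=True) for d in ds]
    n_params = nf  # intercepts
    chosen: list[int] = []
    entry_p: list[float] = []
    r2_path: list[float] = []
    while len(chosen) < max_loci:
        rss = sum(float(r @ r) for r in res_y)
        df2 = n_tot - n_params - nf
        if df2 <= 0 or rss <= 1e-10:
            break
        # ΔRSS for each candidate locus = sum over families of projection gain
        delta = np.zeros(len(grid))
        for f in range(nf):
            ss = (res_d[f] ** 2).sum(axis=1)
            num = res_d[f] @ res_y[f]
            with np.errstate(invalid="ignore", divide="ignore"):
                delta += np.where(ss > 1e-10, num**2 / np.where(ss == 0, 1, ss), 0.0)
        fstat = (delta / nf) / np.maximum((rss - delta) / df2, 1e-300)
        pvals = stats.f.sf(fstat, nf, df2)
        j = int(np.argmin(pvals))
        if pvals[j] >= p_enter or delta[j] <= 0:
            break
        chosen.append(j)
        entry_p.append(float(pvals[j]))
        # update residuals family by family (orthogonalize against the
        # entered column within each family)
        for f in range(nf):
            col = res_d[f][j].copy()
            ss = float(col @ col)
            if ss > 1e-10:
                res_y[f] = res_y[f] - (col @ res_y[f]) / ss * col
                res_d[f] = res_d[f] - np.outer(res_d[f] @ col / ss, col)
        n_params += nf
        rss_new = sum(float(r @ r) for r in res_y)
        r2_path.append(1.0 - rss_new / tss if tss > 0 else 0.0)

    # refit the final model exactly per family for reported effects
    eff_rows = []
    fam_rows = []
    loci_ids = [f"{grid.loc[j, 'chrom']}@{grid.loc[j, 'cm']:g}cM" for j in chosen]
    rss_final = 0.0
    for f, (genos, _y) in enumerate(families):
        y = ys[f]
        x = np.column_stack([np.ones(len(y))] + [ds[f][j] for j in chosen])
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        fam_rows.append({"family": genos.family, "intercept": float(beta[0])})
        resid = y - x @ beta
        rss_final += float(resid @ resid)
        for i, j in enumerate(chosen):
            eff_rows.append(
                {
                    "marker": loci_ids[i],
                    "family": genos.family,
                    "effect": float(-beta[i + 1]),  # P1-positive convention
                    "entry_p": entry_p[i],
                }
            )
    r2 = 1.0 - rss_final / tss if tss > 0 else 0.0
    return JointModel(
        loci=loci_ids,
        effects=pd.DataFrame(eff_rows, columns=["marker", "family", "effect", "entry_p"]),
        family_means=pd.DataFrame(fam_rows, columns=["family", "intercept"]),
        r2=float(r2),
        r2_path=r2_path,
        p_enter=p_enter,
        trait=trait,
    )


def joint_scan(
    families: list[tuple[RILGenotypes, np.ndarray]],
    gmap: pd.DataFrame,
    step_cm: float = 1.0,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
    trait: str = "tco",
) -> tuple[ScanProfile, float, list[QTLResult]]:
    """Family-stratified joint interval scan.

    At each grid point the LOD compares family intercepts only against
    family-nested dosage effects:
    ``LOD = (N / 2) log10(RSS0 / RSS1)`` over the pooled data.  The
    threshold is the ``(1 - alpha)`` quantile of the max-LOD over phenotype
    permutations performed within each family (preserving family structure).
    The reported effect at a grid point is the across-family mean nested
    effect (P1-positive convention).
    """
    families = [(g, y) for g, y in families if len(y) > 0]
    nf = len(families)
    if nf == 0:
        raise ValueError("no families with usable RILs")
    grid = make_grid(gmap, step_cm)
    ys, ds = _family_blocks(families, gmap, grid)
    n_tot = sum(len(y) for y in ys)

    res_y = [y - y.mean() for y in ys]
    res_d = [d - d.mean(axis=1, keepdims=True) for d in ds]
    rss0 = sum(float(r @ r) for r in res_y)
    delta = np.zeros(len(grid))
    eff_sum = np.zeros(len(grid))
    for f in range(nf):
        ss = (res_d[f] ** 2).sum(axis=1)
        num = res_d[f] @ res_y[f]
        with np.errstate(invalid="ignore", divide="ignore"):
            delta += np.where(ss > 1e-10, num**2 / np.where(ss == 0, 1, ss), 0.0)
            eff_sum += np.where(ss > 1e-10, -num / np.where(ss == 0, 1, ss), 0.0)
    ratio = np.clip(1.0 - delta / max(rss0, 1e-300), 1e-12, None)
    lod = -(n_tot / 2.0) * np.log10(ratio)
    frame = grid.copy()
    frame["lod"] = lod
    frame["effect"] = eff_sum / nf
    profile = ScanProfile(frame=frame, cofactors=[], step_cm=step_cm, window_cm=0.0)

    # permutation threshold (within-family shuffles)
    if n_perm * alpha < 1:
        raise ValueError("n_perm * alpha < 1: quantile unresolvable")
    rng = np.random.default_rng(seed)
    delta_p = np.zeros((len(grid), n_perm))
    rss0_p = 0.0
    for f in range(nf):
        y = res_y[f]
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)])  # (P, n)
        perms = perms - perms.mean(axis=1, keepdims=True)
        rss0_p += (perms**2).sum(axis=1)
        ss = (res_d[f] ** 2).sum(axis=1)
        num = res_d[f] @ perms.T  # (G, P)
        with np.errstate(invalid="ignore", divide="ignore"):
            delta_p += np.where(ss[:, None] > 1e-10, num**2 / np.where(ss[:, None] == 0, 1, ss[:, None]), 0.0)
    ratio_p = np.clip(1.0 - delta_p / np.maximum(rss0_p[None, :], 1e-300), 1e-12, None)
    lod_p = -(n_tot / 2.0) * np.log10(ratio_p)
    max_lod = lod_p.max(axis=0)
    order = int(np.ceil((1 - alpha) * n_perm)) - 1
    thr = float(np.sort(max_lod)[order])
    qtl = find_qtl(profile, thr, trait=trait, family="joint", alpha=alpha)
    return profile, thr, qtl


def allele_effect_series(model: JointModel) -> pd.DataFrame:
    """Per-locus summary of family effects.

    For each selected locus: the number of families, the share with a
    positive common-parent effect, and a flag marking an allelic series
    (both effect signs present among families).
    """
    if not model.loci or len(model.effects) == 0:
        return pd.DataFrame(
            columns=["marker", "n_families", "share_positive", "allelic_series"]
        )
    rows = []
    for marker, sub in model.effects.groupby("marker", sort=False):
        eff = sub["effect"].to_numpy(dtype=float)
        pos = eff > 0
        rows.append(
            {
                "marker": marker,
                "n_families": len(eff),
                "share_positive": float(pos.mean()),
                "allelic_series": bool(pos.any() and (eff < 0).any()),
            }
        )
    return pd.DataFrame(rows, columns=["marker", "n_families", "share_positive", "allelic_series"])
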