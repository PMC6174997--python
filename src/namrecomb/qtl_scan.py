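"""Single-family composite interval mapping (CIM) of recombination traits.

The scan is regression-based (Haley–Knott): at each grid position the trait
is regressed on the expected alternate-parent allele dosage given the
flanking observed marker genotypes, on top of a set of cofactor markers
chosen by forward/backward stepwise selection.  Cofactors within a window
of the test position are dropped from the model at that position.  The test
statistic is

    LOD = (n / 2) * log10(RSS_reduced / RSS_full)

comparing the model with and without the dosage term.  Genome-wide
significance thresholds come from permutations of the phenotype (the
originally selected cofactors are reused by default).

Sign convention: the reported additive effect ``a`` is positive when the
common-parent allele increases the trait.

Genotype probabilities use the Haldane map function
``r = (1 - exp(-2 d / 100)) / 2`` with the RIL (selfing, F-infinity)
expansion ``R = 2 r / (1 + 2 r)``, and condition on both flanking
informative markers (two-point Markov approximation); a typed position
returns the observed call and a position with no informative flank returns
the family prior of 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import codes
from .io import RILGenotypes

logger = logging.getLogger(__name__)


def haldane_r(d_cm: "float | np.ndarray") -> "float | np.ndarray":
    """Meiotic recombination fraction for a Haldane map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_expand(r: "float | np.ndarray") -> "float | np.ndarray":
    """Selfed-RIL recombinant fraction ``R = 2r / (1 + 2r)``."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def ril_genotype_prob(
    left_d_cm: float | None,
    left_call: int | None,
    right_d_cm: float | None,
    right_call: int | None,
) -> float:
    """Expected P2-allele dosage at a test position given flanking calls.

    ``left_call`` / ``right_call`` are 0 (P1) or 1 (P2); a ``None`` flank is
    absent.  Distances are cM from the test position to the flank.
    """
    def _p2_weight(d, call):
        big_r = ril_expand(haldane_r(d))
        return (1.0 - big_r) if call == 1 else big_r

    def _p1_weight(d, call):
        big_r = ril_expand(haldane_r(d))
        return (1.0 - big_r) if call == 0 else big_r

    if left_call is None and right_call is None:
        return 0.5
    if left_call is None:
        return float(_p2_weight(right_d_cm, right_call))
    if right_call is None:
        return float(_p2_weight(left_d_cm, left_call))
    w2 = _p2_weight(left_d_cm, left_call) * _p2_weight(right_d_cm, right_call)
    w1 = _p1_weight(left_d_cm, left_call) * _p1_weight(right_d_cm, right_call)
    return float(w2 / (w2 + w1))


def dosage_matrix(
    genos: RILGenotypes,
    gmap: pd.DataFrame,
    grid: pd.DataFrame,
) -> np.ndarray:
    """Expected P2 dosage at every grid position for every RIL.

    ``grid`` has columns ``chrom`` and ``cm``.  Returns an array of shape
    ``(n_grid, n_rils)``.  Vectorized per RIL: at a typed informative marker
    the dosage equals the observed call; elsewhere it is the two-flank
    conditional expectation.
    """
    from .phenotyping import _marker_order

    by_chrom = _marker_order(genos, gmap)
    n = genos.n_rils
    out = np.full((len(grid), n), 0.5)
    gchrom = grid["chrom"].to_numpy()
    gcm = grid["cm"].to_numpy(dtype=float)
    for chrom, (ridx, _mids, cms) in by_chrom.items():
        gsel = np.flatnonzero(gchrom == chrom)
        if gsel.size == 0:
            continue
        gpos = gcm[gsel]
        sub = genos.calls[ridx, :]
        for j in range(n):
            col = sub[:, j]
            inf = (col == codes.P1) | (col == codes.P2)
            if not inf.any():
                continue
            mpos = cms[inf]
            mcall = col[inf].astype(float)  # 0/1
            li = np.searchsorted(mpos, gpos, side="right") - 1
            ri = np.searchsorted(mpos, gpos, side="left")
            has_l = li >= 0
            has_r = ri < len(mpos)
            dl = np.where(has_l, gpos - mpos[np.clip(li, 0, None)], np.inf)
            dr = np.where(has_r, mpos[np.clip(ri, None, len(mpos) - 1)] - gpos, np.inf)
            rl = ril_expand(haldane_r(np.where(np.isfinite(dl), dl, 0.0)))
            rr = ril_expand(haldane_r(np.where(np.isfinite(dr), dr, 0.0)))
            cl = mcall[np.clip(li, 0, None)]
            cr = mcall[np.clip(ri, None, len(mpos) - 1)]
            # per-flank state weights
            w2l = np.where(has_l, np.where(cl == 1, 1 - rl, rl), 1.0)
            w1l = np.where(has_l, np.where(cl == 0, 1 - rl, rl), 1.0)
            w2r = np.where(has_r, np.where(cr == 1, 1 - rr, rr), 1.0)
            w1r = np.where(has_r, np.where(cr == 0, 1 - rr, rr), 1.0)
            w2 = w2l * w2r
            w1 = w1l * w1r
            both_absent = ~has_l & ~has_r
            d = np.where(both_absent, 0.5, w2 / (w2 + w1))
            out[gsel, j] = d
    return out


def make_grid(gmap: pd.DataFrame, step_cm: float = 1.0) -> pd.DataFrame:
    """Scan grid covering each chromosome's mapped span at ``step_cm``."""
    rows = []
    for chrom, sub in gmap.groupby("chrom", sort=False):
        cm = sub["cm"].to_numpy(dtype=float)
        lo, hi = float(cm.min()), float(cm.max())
        pts = np.arange(lo, hi + step_cm / 2, step_cm)
        for p in pts:
            rows.append({"chrom": str(chrom), "cm": float(min(p, hi))})
    return pd.DataFrame(rows)


@dataclass
class ScanProfile:
    """LOD/effect profile over the scan grid plus the cofactors used."""

    frame: pd.DataFrame  # chrom, cm, lod, effect
    cofactors: list[str]
    step_cm: float
    window_cm: float


@dataclass
class QTLResult:
    trait: str
    family: str
    chrom: str
    peak_cm: float
    lod: float
    effect: float  # positive = common-parent allele increases the trait
    ci_lo_cm: float
    ci_hi_cm: float
    threshold: float
    alpha: float


def _stepwise(y: np.ndarray, d_mark: np.ndarray, p_in: float, p_out: float) -> list[int]:
    """Forward selection / backward elimination on marker dosage columns.

    Returns the indices of retained cofactor markers, deterministically
    (ties broken toward the lower index).
    """
    n = len(y)
    m = d_mark.shape[0]
    max_cand = max(2, n // 2 - 2)
    cand = np.arange(m)
    if m > max_cand:
        # pre-thin by marginal strength
        dc = d_mark - d_mark.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        denom = np.sqrt((dc**2).sum(axis=1) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, dc @ yc / np.where(denom == 0, 1, denom), 0.0)
        cand = np.sort(np.argsort(-np.abs(r), kind="stable")[:max_cand])
        logger.info("stepwise: thinned %d candidates to %d by marginal ranking", m, max_cand)
    selected: list[int] = []
    while True:
        changed = False
        # forward step
        x = _design(np.ones((n, 1)), d_mark, selected)
        q, _ = np.linalg.qr(x)
        res_y = y - q @ (q.T @ y)
        rss0 = float(res_y @ res_y)
        k = x.shape[1]
        best_j, best_p = -1, 1.0
        if rss0 > 1e-12 and n - k - 1 > 0:
            rem = [j for j in cand if j not in selected]
            if rem:
                dm = d_mark[rem, :]
                res_d = dm - (dm @ q) @ q.T
                num = res_d @ res_y
                den = np.sqrt((res_d**2).sum(axis=1) * rss0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    r2 = np.where(den > 1e-12, (num / np.where(den == 0, 1, den)) ** 2, 0.0)
                fstat = r2 * (n - k - 1) / np.maximum(1 - r2, 1e-12)
                pvals = stats.f.sf(fstat, 1, n - k - 1)
                jbest = int(np.argmin(pvals))
                if pvals[jbest] < p_in:
                    best_j, best_p = rem[jbest], float(pvals[jbest])
        if best_j >= 0:
            selected.append(best_j)
            changed = True
        # backward step
        while len(selected) > 0:
            x = _design(np.ones((n, 1)), d_mark, selected)
            k = x.shape[1]
            if n - k <= 0:
                selected.pop()
                continue
            worst_i, worst_p = -1, -1.0
            q, _ = np.linalg.qr(x)
            res_y = y - q @ (q.T @ y)
            rss_full = float(res_y @ res_y)
            for i, j in enumerate(selected):
                others = selected[:i] + selected[i + 1 :]
                x0 = _design(np.ones((n, 1)), d_mark, others)
                q0, _ = np.linalg.qr(x0)
                r0 = y - q0 @ (q0.T @ y)
                rss_red = float(r0 @ r0)
                df2 = n - k
                f = max(rss_red - rss_full, 0.0) / max(rss_full / df2, 1e-12)
                p = float(stats.f.sf(f, 1, df2))
                if p > worst_p:
                    worst_i, worst_p = i, p
            if worst_p > p_out:
                selected.pop(worst_i)
                changed = True
            else:
                break
        if not changed:
            break
    return sorted(selected)


def _design(base: np.ndarray, d_mark: np.ndarray, idx: list[int]) -> np.ndarray:
    if not idx:
        return base
    return np.column_stack([base] + [d_mark[j, :] for j in idx])


def select_cofactors(
    y: np.ndarray,
    genos: RILGenotypes,
    gmap: pd.DataFrame,
    p_in: float = 0.01,
    p_out: float = 0.01,
) -> list[str]:
    """Stepwise cofactor selection over the family's markers.

    Marker dosages are the expected P2 dosage at each marker position
    (observed call where typed, flanking-marker expectation where missing).
    Deterministic given the inputs.
    """
    gm = gmap[gmap["marker"].isin(genos.markers)]
    grid = gm.rename(columns={"cm": "cm"})[["chrom", "cm"]].reset_index(drop=True)
    d_mark = dosage_matrix(genos, gmap, grid)
    idx = _stepwise(np.asarray(y, dtype=float), d_mark, p_in, p_out)
    markers = gm["marker"].to_numpy()
    return [str(markers[j]) for j in idx]


def _cofactor_groups(
    grid: pd.DataFrame, cof_pos: pd.DataFrame, window_cm: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group grid rows by which cofactors stay in the model (outside the
    window or on another chromosome).  Returns (grid row indices, active
    cofactor mask) pairs."""
    n_c = len(cof_pos)
    if n_c == 0:
        return [(np.arange(len(grid)), np.zeros(0, dtype=bool))]
    gchrom = grid["chrom"].to_numpy()
    gcm = grid["cm"].to_numpy(dtype=float)
    active = np.ones((len(grid), n_c), dtype=bool)
    for i, (_, row) in enumerate(cof_pos.iterrows()):
        same = gchrom == row["chrom"]
        near = same & (np.abs(gcm - row["cm"]) <= window_cm)
        active[near, i] = False
    groups: dict[bytes, list[int]] = {}
    for g in range(len(grid)):
        groups.setdefault(active[g].tobytes(), []).append(g)
    return [
        (np.asarray(rows), np.frombuffer(key, dtype=bool).copy())
        for key, rows in groups.items()
    ]


def cim_scan(
    y: np.ndarray,
    genos: RILGenotypes,
    gmap: pd.DataFrame,
    cofactors: list[str] | None = None,
    window_cm: float = 10.0,
    step_cm: float = 1.0,
) -> ScanProfile:
    """Composite interval mapping profile for one family and trait.

    ``y`` is aligned with ``genos.rils`` (drop excluded RILs beforehand).
    Cofactor markers within ``window_cm`` of the test position are omitted
    from the model at that position.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 usable RILs, got {n}")
    if n != genos.n_rils:
        raise ValueError("phenotype length does not match RIL count")
    cofactors = cofactors or []
    grid = make_grid(gmap[gmap["marker"].isin(genos.markers)], step_cm)
    d_grid = dosage_matrix(genos, gmap, grid)
    gm = gmap.set_index("marker")
    cof_pos = gm.loc[cofactors, ["chrom", "cm"]].reset_index() if cofactors else pd.DataFrame(columns=["marker", "chrom", "cm"])
    cof_grid = cof_pos.rename(columns={"cm": "cm"})[["chrom", "cm"]]
    d_cof = dosage_matrix(genos, gmap, cof_grid) if len(cof_grid) else np.zeros((0, n))

    lod = np.zeros(len(grid))
    effect = np.zeros(len(grid))
    for rows, mask in _cofactor_groups(grid, cof_pos, window_cm):
        x = np.column_stack([np.ones(n)] + [d_cof[i] for i in np.flatnonzero(mask)])
        q, _ = np.linalg.qr(x)
        res_y = y - q @ (q.T @ y)
        rss0 = float(res_y @ res_y)
        dm = d_grid[rows, :]
        res_d = dm - (dm @ q) @ q.T
        ss_d = (res_d**2).sum(axis=1)
        num = res_d @ res_y
        with np.errstate(invalid="ignore", divide="ignore"):
            b = np.where(ss_d > 1e-12, num / np.where(ss_d == 0, 1, ss_d), 0.0)
            r2 = np.where((ss_d > 1e-12) & (rss0 > 1e-12), num**2 / (ss_d * max(rss0, 1e-300)), 0.0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
        lod[rows] = -(n / 2.0) * np.log10(1.0 - r2)
        effect[rows] = -b  # dosage counts P2 alleles; report P1-positive
    frame = grid.copy()
    frame["lod"] = lod
    frame["effect"] = effect
    return ScanProfile(frame=frame, cofactors=list(cofactors), step_cm=step_cm, window_cm=window_cm)


def permutation_threshold(
    y: np.ndarray,
    genos: RILGenotypes,
    gmap: pd.DataFrame,
    cofactors: list[str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    window_cm: float = 10.0,
    step_cm: float = 1.0,
    reselect: bool = False,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The threshold is the ``(1 - alpha)`` empirical quantile (order statistic
    ``ceil((1 - alpha) n_perm)``) of the max-LOD over ``n_perm`` scans with
    the phenotype permuted against the genotypes.  By default the originally
    selected cofactors are kept fixed across permutations (fast, but mildly
    anticonservative because data-selected cofactors deflate the permuted
    max-LOD); ``reselect=True`` redoes the stepwise selection for every
    permutation.  ``n_perm * alpha < 1`` is rejected because the quantile
    would sit beyond the largest order statistic.
    """
    if n_perm * alpha < 1:
        raise ValueError("n_perm * alpha < 1: quantile unresolvable")
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])  # (n_perm, n)
    if reselect:
        max_lod = np.empty(n_perm)
        for i in range(n_perm):
            cof_i = select_cofactors(perms[i], genos, gmap)
            prof = cim_scan(perms[i], genos, gmap, cof_i, window_cm, step_cm)
            max_lod[i] = float(prof.frame["lod"].max())
        order = int(np.ceil((1 - alpha) * n_perm)) - 1
        return float(np.sort(max_lod)[order])
    cofactors = cofactors or []
    grid = make_grid(gmap[gmap["marker"].isin(genos.markers)], step_cm)
    d_grid = dosage_matrix(genos, gmap, grid)
    gm = gmap.set_index("marker")
    cof_pos = gm.loc[cofactors, ["chrom", "cm"]].reset_index() if cofactors else pd.DataFrame(columns=["marker", "chrom", "cm"])
    d_cof = dosage_matrix(genos, gmap, cof_pos[["chrom", "cm"]]) if len(cof_pos) else np.zeros((0, n))

    max_lod = np.zeros(n_perm)
    for rows, mask in _cofactor_groups(grid, cof_pos, window_cm):
        x = np.column_stack([np.ones(n)] + [d_cof[i] for i in np.flatnonzero(mask)])
        q, _ = np.linalg.qr(x)
        res_p = perms - (perms @ q) @ q.T  # (n_perm, n)
        rss0 = (res_p**2).sum(axis=1)  # (n_perm,)
        dm = d_grid[rows, :]
        res_d = dm - (dm @ q) @ q.T
        ss_d = (res_d**2).sum(axis=1)  # (n_rows,)
        num = res_d @ res_p.T  # (n_rows, n_perm)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = num**2 / (ss_d[:, None] * rss0[None, :])
        r2 = np.nan_to_num(np.clip(r2, 0.0, 1.0 - 1e-12))
        lod = -(n / 2.0) * np.log10(1.0 - r2)
        max_lod = np.maximum(max_lod, lod.max(axis=0))
    order = int(np.ceil((1 - alpha) * n_perm)) - 1
    return float(np.sort(max_lod)[order])


def find_qtl(
    profile: ScanProfile,
    threshold: float,
    drop: float = 2.0,
    min_separation_cm: float = 20.0,
    trait: str = "tco",
    family: str = "",
    alpha: float = 0.05,
) -> list[QTLResult]:
    """Peaks above the threshold with 2-LOD support intervals.

    Local maxima above the threshold are accepted in descending LOD order;
    a candidate is merged into an already-accepted peak unless it is at
    least ``min_separation_cm`` away or the valley between them falls at
    least ``drop`` below the lower of the two peaks.  The support interval
    is the contiguous run of grid positions around the peak with
    ``LOD >= peak - drop``.
    """
    results: list[QTLResult] = []
    for chrom, sub in profile.frame.groupby("chrom", sort=False):
        cm = sub["cm"].to_numpy(dtype=float)
        lod = sub["lod"].to_numpy(dtype=float)
        eff = sub["effect"].to_numpy(dtype=float)
        if len(cm) < 1:
            continue
        is_peak = np.ones(len(cm), dtype=bool)
        if len(cm) > 1:
            is_peak[:-1] &= lod[:-1] >= lod[1:]
            is_peak[1:] &= lod[1:] >= lod[:-1]
        cand = [i for i in np.flatnonzero(is_peak & (lod > threshold))]
        cand.sort(key=lambda i: (-lod[i], cm[i]))
        accepted: list[int] = []
        for i in cand:
            ok = True
            for j in accepted:
                lo_i, hi_i = min(i, j), max(i, j)
                valley = lod[lo_i : hi_i + 1].min()
                lower_peak = min(lod[i], lod[j])
                separated = (abs(cm[i] - cm[j]) >= min_separation_cm) or (
                    valley <= lower_peak - drop
                )
                if not separated:
                    ok = False
                    break
            if ok:
                accepted.append(i)
        for i in sorted(accepted, key=lambda i: cm[i]):
            lo = i
            while lo > 0 and lod[lo - 1] >= lod[i] - drop:
                lo -= 1
            hi = i
            while hi < len(cm) - 1 and lod[hi + 1] >= lod[i] - drop:
                hi += 1
            results.append(
                QTLResult(
                    trait=trait,
                    family=family,
                    chrom=str(chrom),
                    peak_cm=float(cm[i]),
                    lod=float(lod[i]),
                    effect=float(eff[i]),
                    ci_lo_cm=float(cm[lo]),
                    ci_hi_cm=float(cm[hi]),
                    threshold=float(threshold),
                    alpha=alpha,
                )
            )
    return results


def scan_family(
    pheno: pd.DataFrame,
    genos: RILGenotypes,
    gmap: pd.DataFrame,
    trait: str = "tco",
    alpha: float = 0.05,
    n_perm: int = 200,
    window_cm: float = 10.0,
    step_cm: float = 1.0,
    seed: int | None = None,
    p_in: float = 0.01,
    p_out: float = 0.01,
    select: bool = True,
) -> tuple[ScanProfile, float, list[QTLResult]]:
    """Convenience wrapper: drop excluded RILs, select cofactors, scan,
    permute for the threshold, and report QTL."""
    usable = ~pheno["excluded"].to_numpy(dtype=bool)
    keep = [r for r, u in zip(genos.rils, usable) if u]
    sub = _subset_rils(genos, keep)
    y = pheno.loc[keep, trait].to_numpy(dtype=float)
    cof = select_cofactors(y, sub, gmap, p_in, p_out) if select else []
    profile = cim_scan(y, sub, gmap, cof, window_cm, step_cm)
    thr = permutation_threshold(
        y, sub, gmap, cof, n_perm=n_perm, alpha=alpha, seed=seed,
        window_cm=window_cm, step_cm=step_cm,
    )
    qtl = find_qtl(profile, thr, trait=trait, family=genos.family, alpha=alpha)
    return profile, thr, qtl


def _subset_rils(genos: RILGenotypes, keep: list[str]) -> RILGenotypes:
    idx = [genos.rils.index(r) for r in keep]
    return RILGenotypes(
        family=genos.family,
        common_parent=genos.common_parent,
        alt_parent=genos.alt_parent,
        markers=list(genos.markers),
        rils=list(keep),
        calls=genos.calls[:, idx],
    )
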