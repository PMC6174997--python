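import numpy as np
import pandas as pd
import pytest

import namrecomb as nr
from namrecomb import codes
from namrecomb.qtl_scan import (
    ScanProfile,
    cim_scan,
    dosage_matrix,
    find_qtl,
    haldane_r,
    make_grid,
    permutation_threshold,
    ril_genotype_prob,
    ril_expand,
    select_cofactors,
)

from conftest import toy_genotypes, toy_map


class TestGenotypeProb:
    def test_typed_marker_returns_observed_call(self):
        assert ril_genotype_prob(0.0, 1, 5.0, 0) == pytest.approx(1.0)
        assert ril_genotype_prob(3.0, 0, 0.0, 0) == pytest.approx(0.0)

    def test_no_flanks_gives_prior(self):
        assert ril_genotype_prob(None, None, None, None) == 0.5

    def test_matching_close_flanks_pin_the_genotype(self):
        # flanks both P1 at 0.5 cM each side: switch is vanishingly unlikely
        assert ril_genotype_prob(0.5, 0, 0.5, 0) < 0.01

    @pytest.mark.parametrize("dl,dr,gl,gr", [
        (1.0, 2.0, 0, 0), (5.0, 5.0, 0, 1), (0.5, 9.0, 1, 1), (3.0, 1.0, 1, 0),
    ])
    def test_matches_two_state_chain_enumeration(self, dl, dr, gl, gr):
        # independent oracle: enumerate the two hidden states with symmetric
        # transition probabilities given by the RIL-expanded Haldane fraction
        def big_r(d):
            r = 0.5 * (1 - np.exp(-2 * d / 100))
            return 2 * r / (1 + 2 * r)

        pl, pr = big_r(dl), big_r(dr)
        w = {}
        for state in (0, 1):
            a = (1 - pl) if state == gl else pl
            b = (1 - pr) if state == gr else pr
            w[state] = a * b
        expected = w[1] / (w[0] + w[1])
        assert ril_genotype_prob(dl, gl, dr, gr) == pytest.approx(expected, abs=1e-12)

    def test_dosage_matrix_agrees_with_scalar(self):
        genos = toy_genotypes({"m0": "AB", "m1": "NN", "m2": "BA"})
        gmap = toy_map(["m0", "m1", "m2"], spacing=10.0)
        grid = pd.DataFrame({"chrom": ["c1"] * 3, "cm": [0.0, 10.0, 15.0]})
        d = dosage_matrix(genos, gmap, grid)
        assert d[0, 0] == pytest.approx(0.0)
        assert d[0, 1] == pytest.approx(1.0)
        # m1 missing: interior point conditioned on m0/m2 only
        assert d[1, 0] == pytest.approx(ril_genotype_prob(10.0, 0, 10.0, 1))
        assert d[2, 0] == pytest.approx(ril_genotype_prob(15.0, 0, 5.0, 1))


def _assoc_family(n=120, effect=2.0, sd=1.0, seed=5, n_markers=30, spacing=5.0):
    # linked RIL-style mosaic: adjacent markers switch phase with the
    # RIL-expanded Haldane fraction for the given spacing
    rng = np.random.default_rng(seed)
    markers = [f"m{i:02d}" for i in range(n_markers)]
    big_r = float(ril_expand(haldane_r(spacing)))
    switches = rng.random((n_markers - 1, n)) < big_r
    start = rng.integers(0, 2, size=(1, n))
    calls = (np.vstack([start, switches]).cumsum(axis=0) % 2).astype(np.int8)
    genos = nr.RILGenotypes(
        family="fam", common_parent="P1", alt_parent="P2",
        markers=markers, rils=[f"r{i}" for i in range(n)], calls=calls,
    )
    gmap = toy_map(markers, spacing=spacing)
    y = effect * calls[n_markers // 2].astype(float) + rng.normal(0, sd, n)
    return genos, gmap, y, markers[n_markers // 2]


class TestCIMScan:
    def test_constant_phenotype_gives_zero_lod(self):
        genos, gmap, _y, _m = _assoc_family()
        prof = cim_scan(np.full(genos.n_rils, 7.0), genos, gmap)
        assert np.allclose(prof.frame["lod"], 0.0)

    def test_lod_matches_direct_regression_oracle(self):
        import statsmodels.api as sm

        genos, gmap, y, marker = _assoc_family()
        prof = cim_scan(y, genos, gmap, cofactors=[], step_cm=5.0)
        i = genos.markers.index(marker)
        x = genos.calls[i].astype(float)
        full = sm.OLS(y, sm.add_constant(x)).fit()
        null = sm.OLS(y, np.ones_like(y)).fit()
        lod_direct = (len(y) / 2) * np.log10(null.ssr / full.ssr)
        at = prof.frame[(prof.frame["chrom"] == "c1")
                        & (prof.frame["cm"] == gmap.set_index("marker").loc[marker, "cm"])]
        assert at["lod"].iloc[0] == pytest.approx(lod_direct, rel=1e-9)
        # effect sign: P2 carriers higher -> common-parent effect negative
        assert at["effect"].iloc[0] == pytest.approx(-full.params[1], rel=1e-9)

    def test_lod_invariant_under_affine_rescaling(self):
        genos, gmap, y, _m = _assoc_family()
        a = cim_scan(y, genos, gmap).frame["lod"]
        b = cim_scan(3.5 * y - 11.0, genos, gmap).frame["lod"]
        assert np.allclose(a, b)

    def test_too_few_rils_rejected(self):
        genos, gmap, y, _m = _assoc_family(n=8)
        with pytest.raises(ValueError, match="10"):
            cim_scan(y, genos, gmap)


class TestCofactors:
    def test_null_entry_matches_marginal_p_oracle(self):
        # on pure noise the first forward step enters a marker iff the
        # smallest marginal F-test p-value beats p_in; check the stepwise
        # decision against an independent computation of that oracle
        from scipy import stats as ss

        agree = 0
        empties = oracle_empties = 0
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            genos, gmap, _y, _m = _assoc_family(n=200, n_markers=50, seed=seed)
            y = rng.normal(0, 1, 200)
            sel = select_cofactors(y, genos, gmap)
            c = genos.calls.astype(float)
            dc = c - c.mean(axis=1, keepdims=True)
            yc = y - y.mean()
            r2 = (dc @ yc) ** 2 / ((dc**2).sum(axis=1) * (yc**2).sum())
            pmin = ss.f.sf(r2 * 198 / (1 - r2), 1, 198).min()
            empties += not sel
            oracle_empties += pmin >= 0.01
            agree += (not sel) == (pmin >= 0.01)
        assert agree == 12
        assert empties == oracle_empties

    def test_strong_marker_selected_and_deterministic(self):
        genos, gmap, y, marker = _assoc_family(effect=2.0, sd=1.0)
        first = select_cofactors(y, genos, gmap)
        assert marker in first
        assert select_cofactors(y, genos, gmap) == first


class TestPermutationThreshold:
    def test_determinism_and_alpha_ordering(self):
        genos, gmap, y, _m = _assoc_family()
        kw = dict(n_perm=100, seed=42, step_cm=5.0)
        t1 = permutation_threshold(y, genos, gmap, alpha=0.05, **kw)
        t2 = permutation_threshold(y, genos, gmap, alpha=0.05, **kw)
        strict = permutation_threshold(y, genos, gmap, alpha=0.01, **kw)
        assert t1 == t2
        assert strict >= t1

    def test_unresolvable_quantile_rejected(self):
        genos, gmap, y, _m = _assoc_family()
        with pytest.raises(ValueError):
            permutation_threshold(y, genos, gmap, n_perm=100, alpha=0.001)


def _profile(chrom_lod: dict[str, list[float]], step=1.0) -> ScanProfile:
    rows = []
    for chrom, lods in chrom_lod.items():
        for i, l in enumerate(lods):
            rows.append({"chrom": chrom, "cm": i * step, "lod": l, "effect": 1.0})
    return ScanProfile(frame=pd.DataFrame(rows), cofactors=[], step_cm=step, window_cm=10.0)


class TestFindQTL:
    def test_support_interval_by_two_lod_drop(self):
        lods = [0.0] * 40 + [6.5, 7.0, 7.5, 8.0, 7.5, 7.0, 6.5] + [0.0] * 20
        prof = _profile({"c1": lods})
        qtl = find_qtl(prof, threshold=6.0)
        assert len(qtl) == 1
        q = qtl[0]
        assert q.peak_cm == 43.0 and q.lod == 8.0
        assert (q.ci_lo_cm, q.ci_hi_cm) == (40.0, 46.0)

    def test_below_threshold_empty(self):
        prof = _profile({"c1": [1.0, 2.0, 1.0]})
        assert find_qtl(prof, threshold=3.0) == []

    def test_two_separated_peaks(self):
        lods = [0.0] * 10 + [8.0] + [3.0] * 60 + [7.0] + [0.0] * 10
        prof = _profile({"c1": lods})
        qtl = find_qtl(prof, threshold=5.0, drop=2.0, min_separation_cm=20.0)
        assert len(qtl) == 2
        assert {q.peak_cm for q in qtl} == {10.0, 71.0}

    def test_close_shoulder_merged_into_main_peak(self):
        lods = [0.0] * 10 + [8.0, 7.9, 7.8, 7.9, 7.7] + [0.0] * 10
        prof = _profile({"c1": lods})
        qtl = find_qtl(prof, threshold=5.0)
        assert len(qtl) == 1 and qtl[0].peak_cm == 10.0
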