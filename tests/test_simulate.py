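import numpy as np
import pandas as pd
import pytest

import namrecomb as nr
from namrecomb import codes
from namrecomb.genome import ArmPartition
from namrecomb.simulate import (
    ModifierSpec,
    gamete,
    simulate_annotation,
    simulate_founders,
    simulate_ssd_family,
)


@pytest.fixture(scope="module")
def model():
    return nr.uniform_genome(2, 100.0, 101)


class TestFounders:
    def test_determinism(self, model):
        a = simulate_founders(model, 5, seed=3)
        b = simulate_founders(model, 5, seed=3)
        assert np.array_equal(a.alleles, b.alleles)
        pd.testing.assert_frame_equal(a.ibd_tracts, b.ibd_tracts)

    def test_too_few_founders(self, model):
        with pytest.raises(ValueError):
            simulate_founders(model, 1)

    def test_fixed_maf_mean(self, model):
        panel = simulate_founders(model, 30, maf_law=0.5, seed=4)
        n = panel.alleles.size
        se = 0.5 / np.sqrt(n)
        assert abs(panel.alleles.mean() - 0.5) < 3 * se

    def test_no_ibd_means_no_tracts(self, model):
        panel = simulate_founders(model, 4, ibd_fraction=0.0, seed=5)
        assert len(panel.ibd_tracts) == 0

    def test_realized_ibd_fraction(self, model):
        frac = 0.3
        panel = simulate_founders(model, 25, ibd_fraction=frac, seed=6,
                                  mean_tract_cm=15.0)
        total = model.total_length_cm
        assert len(panel.ibd_tracts) >= 20
        for f in panel.founders[1:]:
            sub = panel.ibd_tracts[panel.ibd_tracts["founder"] == f]
            got = (sub["end_cm"] - sub["start_cm"]).sum() / total
            assert frac * 0.8 <= got <= frac * 1.2

    def test_ibd_tracts_copy_common_parent(self, model):
        panel = simulate_founders(model, 4, ibd_fraction=0.4, seed=7)
        off = 0
        for c in model.chromosomes:
            pos = model.markers[c.name]
            for _, tr in panel.ibd_tracts[panel.ibd_tracts["chrom"] == c.name].iterrows():
                fi = panel.founder_index(tr["founder"])
                sel = (pos >= tr["start_cm"]) & (pos < tr["end_cm"])
                assert np.array_equal(
                    panel.alleles[fi, off : off + len(pos)][sel],
                    panel.alleles[0, off : off + len(pos)][sel],
                )
            off += len(pos)


class TestMeiosis:
    def test_poisson_crossover_mean(self):
        rng = np.random.default_rng(8)
        hap_a = (np.array([0.0]), np.array([0], dtype=np.int8))
        hap_b = (np.array([0.0]), np.array([1], dtype=np.int8))
        counts = [len(gamete(rng, hap_a, hap_b, 100.0)[1]) for _ in range(4000)]
        se = np.sqrt(1.0 / 4000)
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_homozygous_parent_gamete_identical(self):
        rng = np.random.default_rng(9)
        hap = (np.array([0.0, 40.0]), np.array([0, 1], dtype=np.int8))
        for _ in range(20):
            (bp, org), _xo = gamete(rng, hap, hap, 100.0)
            assert np.array_equal(bp, hap[0]) and np.array_equal(org, hap[1])

    def test_region_targeted_multiplier(self):
        # doubling only the middle region leaves the flanks untouched
        rng = np.random.default_rng(10)
        hap_a = (np.array([0.0]), np.array([0], dtype=np.int8))
        hap_b = (np.array([0.0]), np.array([1], dtype=np.int8))
        regions = [(0.0, 30.0, 1.0), (30.0, 70.0, 2.0), (70.0, 100.0, 1.0)]
        mid, flank = 0, 0
        n = 6000
        for _ in range(n):
            _g, xo = gamete(rng, hap_a, hap_b, 100.0, regions=regions)
            for p in xo:
                if 30.0 <= p < 70.0:
                    mid += 1
                else:
                    flank += 1
        # expected: mid 2 * 0.4 = 0.8 per meiosis, flanks 0.6
        assert abs(mid / n - 0.8) < 3 * np.sqrt(0.8 / n)
        assert abs(flank / n - 0.6) < 3 * np.sqrt(0.6 / n)

    def test_nonpositive_multiplier_rejected(self):
        rng = np.random.default_rng(11)
        hap = (np.array([0.0]), np.array([0], dtype=np.int8))
        with pytest.raises(ValueError):
            gamete(rng, hap, hap, 100.0, regions=[(0.0, 100.0, -1.0)])


class TestSSDFamily:
    def test_determinism(self, model):
        panel = nr.divergent_panel(model)
        a = simulate_ssd_family(panel, "F01", 20, 7, model, seed=12)
        b = simulate_ssd_family(panel, "F01", 20, 7, model, seed=12)
        assert np.array_equal(a[0].calls, b[0].calls)
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_residual_heterozygosity_rate(self):
        from namrecomb.experiments import residual_heterozygosity

        r = residual_heterozygosity(seed=2, n_rils=800)
        # binomial SE understates (linked loci); allow 25% relative slack
        assert r["het_freq"] == pytest.approx(r["expected"], rel=0.25)

    def test_generations_precondition(self, model):
        panel = nr.divergent_panel(model)
        with pytest.raises(ValueError):
            simulate_ssd_family(panel, "F01", 5, 1, model, seed=1)

    def test_modifier_off_map_rejected(self, model):
        panel = nr.divergent_panel(model)
        bad = ModifierSpec(chrom="chr1", pos_cm=500.0, beta=0.1)
        with pytest.raises(ValueError):
            simulate_ssd_family(panel, "F01", 5, 7, model, [bad], seed=1)
        with pytest.raises(KeyError):
            simulate_ssd_family(
                panel, "F01", 5, 7, model,
                [ModifierSpec(chrom="nope", pos_cm=1.0, beta=0.1)], seed=1,
            )

    def test_truth_counts_consistent(self, small_family):
        truth = small_family["truth"]
        chrom_cols = [c for c in truth.columns if c.startswith("co_")]
        assert (truth[chrom_cols].sum(axis=1) == truth["tco_true"]).all()
        by_ril = small_family["truth_cos"].groupby("ril").size()
        merged = by_ril.reindex(truth["ril"]).fillna(0).astype(int)
        assert np.array_equal(merged.to_numpy(), truth["tco_true"].to_numpy())

    def test_modifier_raises_family_crossovers(self, model):
        panel = nr.divergent_panel(model)
        spec = ModifierSpec(chrom="chr1", pos_cm=50.0, beta=1.0, scope="global",
                            carriers=frozenset(("F01",)))
        _g, _c, base = simulate_ssd_family(panel, "F01", 400, 7, model, seed=13)
        _g, _c, mod = simulate_ssd_family(panel, "F01", 400, 7, model, [spec], seed=13)
        assert mod["tco_true"].mean() > base["tco_true"].mean()
        hi = mod.loc[mod["dosage_0"] == 1.0, "tco_true"].mean()
        lo = mod.loc[mod["dosage_0"] == 0.0, "tco_true"].mean()
        assert hi > lo

    def test_chromosome_scope_targets_own_chromosome_only(self, model):
        panel = nr.divergent_panel(model)
        spec = ModifierSpec(chrom="chr1", pos_cm=50.0, beta=1.5,
                            scope="chromosome", carriers=frozenset(("F01",)))
        _g, _c, truth = simulate_ssd_family(panel, "F01", 2000, 7, model, [spec], seed=14)
        hi = truth[truth["dosage_0"] == 1.0]
        lo = truth[truth["dosage_0"] == 0.0]

        def z(col):
            d = hi[col].mean() - lo[col].mean()
            se = np.sqrt(hi[col].var() / len(hi) + lo[col].var() / len(lo))
            return d / se

        assert z("co_chr1") > 4.0  # strong targeted increase
        assert abs(z("co_chr2")) < 3.0  # untargeted chromosome untouched


class TestNoise:
    def test_zero_rates_identity(self, small_family):
        genos = small_family["genos"]
        out = nr.add_genotyping_noise(genos, 0.0, 0.0, seed=1)
        assert np.array_equal(out.calls, genos.calls)

    def test_flip_count_binomial(self, small_family):
        genos = small_family["genos"]
        out = nr.add_genotyping_noise(genos, 0.01, 0.0, seed=2)
        hom = (genos.calls == codes.P1) | (genos.calls == codes.P2)
        flips = int((out.calls != genos.calls)[hom].sum())
        n = int(hom.sum())
        assert abs(flips - 0.01 * n) < 3 * np.sqrt(0.01 * 0.99 * n)

    def test_determinism(self, small_family):
        genos = small_family["genos"]
        a = nr.add_genotyping_noise(genos, 0.02, 0.05, seed=3)
        b = nr.add_genotyping_noise(genos, 0.02, 0.05, seed=3)
        assert np.array_equal(a.calls, b.calls)

    @pytest.mark.parametrize("err,miss", [(-0.1, 0.0), (0.0, 1.5)])
    def test_rates_validated(self, small_family, err, miss):
        with pytest.raises(ValueError):
            nr.add_genotyping_noise(small_family["genos"], err, miss)


@pytest.fixture()
def bins():
    return pd.DataFrame(
        {
            "chrom": ["c1"] * 10,
            "bin": range(10),
            "high_recomb": [True, True] + [False] * 6 + [True, True],
        }
    )


class TestAnnotation:
    def test_null_theta_uniform(self, bins):
        ann = simulate_annotation(bins, 1.0, 10_000, seed=5)
        high = ann["bin"].isin([0, 1, 8, 9])
        p1 = ann.loc[high, "deleterious"].mean()
        p2 = ann.loc[~high, "deleterious"].mean()
        se = np.sqrt(0.05 * 0.95 * (1 / high.sum() + 1 / (~high).sum()))
        assert abs(p1 - p2) < 3 * se

    def test_theta_two_odds_ratio(self, bins):
        ann = simulate_annotation(bins, 2.0, 40_000, seed=6)
        high = ann["bin"].isin([0, 1, 8, 9])
        d_hi = ann.loc[high, "deleterious"].mean()
        d_lo = ann.loc[~high, "deleterious"].mean()
        odds = (d_lo / (1 - d_lo)) / (d_hi / (1 - d_hi))
        assert odds == pytest.approx(2.0, rel=0.2)

    def test_empty_and_invalid(self, bins):
        assert len(simulate_annotation(bins, 1.0, 0, seed=1)) == 0
        with pytest.raises(ValueError):
            simulate_annotation(bins, 0.0, 10, seed=1)
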