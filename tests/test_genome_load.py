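import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import namrecomb as nr
from namrecomb.genome_load import (
    annotation_to_bin_counts,
    define_high_recomb_regions,
    ibd_co_contrast,
    ld_per_bin,
    ld_recomb_correlation,
    load_contrast,
    make_bins,
)


def _bins(d_hi, n_hi, d_lo, n_lo):
    return pd.DataFrame(
        {
            "high_recomb": [True, False],
            "deleterious": [d_hi, d_lo],
            "non_deleterious": [n_hi, n_lo],
        }
    )


def brute_force_fisher_less(table: np.ndarray) -> float:
    """One-sided Fisher p by exhaustive enumeration of the hypergeometric
    tables with the same margins and at most the observed top-left cell."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    from math import comb

    denom = comb(n, col1)
    p = 0.0
    for x in range(0, a + 1):
        if col1 - x <= c + d and row1 - x >= 0 and col1 - x >= 0:
            p += comb(row1, x) * comb(n - row1, col1 - x) / denom
    return p


class TestLoadContrast:
    def test_p_matches_exhaustive_hypergeometric_tail(self):
        res = load_contrast(_bins(10, 190, 30, 170))
        assert res["p"] == pytest.approx(brute_force_fisher_less(res["table"]), rel=1e-9)

    def test_proportion_arithmetic(self):
        res = load_contrast(_bins(10, 100, 50, 100))
        assert res["prop_high"] == pytest.approx(10 / 110, abs=1e-6)

    def test_equal_proportions_not_significant(self):
        res = load_contrast(_bins(20, 180, 20, 180))
        assert res["p"] > 0.05

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            load_contrast(_bins(0, 0, 10, 10))


class TestHighRecombRegions:
    def test_positional_flagging(self):
        bins = pd.DataFrame(
            {"chrom": "c1", "bin": [0, 1, 2], "mid_scaled": [0.03, 0.5, 0.97],
             "n_co": [40, 10, 40]}
        )
        out, frac = define_high_recomb_regions(bins, 10.0)
        assert out["high_recomb"].tolist() == [True, False, True]
        assert frac == pytest.approx(80 / 90)

    def test_pct_bounds(self):
        bins = pd.DataFrame({"chrom": [], "bin": [], "mid_scaled": [], "n_co": []})
        with pytest.raises(ValueError):
            define_high_recomb_regions(bins, 60.0)

    def test_distal_skewed_simulation_captures_majority(self, small_family):
        # simulated distal-skewed intensity concentrates COs in the flagged ends
        from namrecomb.experiments import ld_recomb_study  # noqa: F401  (shape only)

        bins = make_bins(small_family["model"], small_family["truth_cos"], 10)
        out, frac = define_high_recomb_regions(bins, 10.0)
        # uniform intensity: captured fraction ~ flagged length share (20%)
        assert frac == pytest.approx(0.2, abs=0.07)


class TestLDPerBin:
    def test_duplicate_columns_full_ld(self):
        x = np.array([[0, 0, 1], [1, 1, 0], [0, 0, 1], [1, 1, 1]])
        mb = pd.DataFrame({"chrom": "c1", "bin": [0, 0, 0]})
        out = ld_per_bin(x, mb)
        # markers 0 and 1 identical -> r2 = 1 contributes; third independent
        assert out.loc[0, "mean_r2"] <= 1.0
        only_dups = ld_per_bin(x[:, :2], pd.DataFrame({"chrom": "c1", "bin": [0, 0]}))
        assert only_dups.loc[0, "mean_r2"] == pytest.approx(1.0)

    def test_monomorphic_markers_excluded(self):
        x = np.array([[0, 1, 0], [0, 0, 1], [0, 1, 1], [0, 0, 0]])
        mb = pd.DataFrame({"chrom": "c1", "bin": [0, 0, 0]})
        out = ld_per_bin(x, mb)
        assert out.loc[0, "n_markers"] == 2

    def test_independent_markers_finite_sample_r2(self):
        # E[r^2] for independent loci across n founders is ~ 1/(n-1)
        rng = np.random.default_rng(12)
        n = 30
        x = (rng.random((n, 400)) < 0.5).astype(int)
        mb = pd.DataFrame({"chrom": "c1", "bin": np.repeat(np.arange(8), 50)})
        out = ld_per_bin(x, mb)
        assert out["mean_r2"].mean() == pytest.approx(1 / (n - 1), rel=0.25)


class TestLDRecombCorrelation:
    def test_collinear_toy_gives_minus_one(self):
        bins = pd.DataFrame({"mean_r2": [1.0, 0.55, 0.1], "n_co": [1, 5, 9]})
        r, p = ld_recomb_correlation(bins)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_permuted_labels_near_zero(self):
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(30):
            bins = pd.DataFrame(
                {"mean_r2": rng.permutation(np.linspace(0.1, 0.9, 20)),
                 "n_co": np.arange(20)}
            )
            rs.append(ld_recomb_correlation(bins)[0])
        assert abs(np.mean(rs)) < 0.12

    def test_errors(self):
        with pytest.raises(ValueError):
            ld_recomb_correlation(pd.DataFrame({"mean_r2": [0.1], "n_co": [1]}))
        with pytest.raises(ValueError):
            ld_recomb_correlation(
                pd.DataFrame({"mean_r2": [0.5, 0.5, 0.5], "n_co": [1, 2, 3]})
            )


def brute_force_u(x, y):
    u = 0.0
    for a, b in itertools.product(x, y):
        u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


class TestIBDContrast:
    def _inputs(self, ibd_counts, non_counts):
        regions = pd.DataFrame(
            {
                "chrom": "c1",
                "start_cm": np.arange(len(ibd_counts) + len(non_counts)) * 10.0,
                "end_cm": np.arange(1, len(ibd_counts) + len(non_counts) + 1) * 10.0,
            }
        )
        tracts = pd.DataFrame(
            {
                "founder": "F01",
                "chrom": "c1",
                "start_cm": [0.0],
                "end_cm": [len(ibd_counts) * 10.0],
            }
        )
        rows = []
        for i, c in enumerate(list(ibd_counts) + list(non_counts)):
            for j in range(c):
                rows.append({"family": "fam", "chrom": "c1",
                             "pos_cm": i * 10.0 + j * 0.01 + 0.5, "ril": f"r{j}"})
        cos = pd.DataFrame(rows, columns=["family", "chrom", "pos_cm", "ril"])
        return tracts, cos, regions

    @pytest.mark.parametrize(
        "ibd,non",
        [([1, 2], [3, 4]), ([3, 4], [1, 2]), ([2, 2, 5], [2, 4]), ([0, 7, 1], [3, 3, 3])],
    )
    def test_u_matches_exhaustive_pair_counting(self, ibd, non):
        tracts, cos, regions = self._inputs(ibd, non)
        res = ibd_co_contrast(tracts, cos, regions, {"fam": "F01"})
        assert res["u"] == pytest.approx(brute_force_u(ibd, non))

    def test_identical_samples_null(self):
        tracts, cos, regions = self._inputs([3, 3, 3], [3, 3, 3])
        res = ibd_co_contrast(tracts, cos, regions, {"fam": "F01"},
                              alternative="two-sided")
        assert res["p"] == pytest.approx(1.0, abs=0.05)

    def test_empty_sample_rejected(self):
        tracts, cos, regions = self._inputs([1, 2], [3, 4])
        with pytest.raises(ValueError):
            ibd_co_contrast(tracts.iloc[0:0], cos, regions, {"fam": "F01"})
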