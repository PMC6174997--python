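import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import namrecomb as nr
from namrecomb import codes
from namrecomb.genome import ArmPartition, build_genome_model
from namrecomb.phenotyping import (
    breakpoint_distribution,
    call_crossovers,
    collapse_redundant_markers,
    estimate_map_length,
    exclude_regions,
    map_summary,
    summarize_phenotypes,
    thinning_experiment,
)

from conftest import toy_genotypes, toy_map


def _single_ril(calls: str):
    genos = toy_genotypes({f"m{i}": c for i, c in enumerate(calls)}, rils=None)
    # toy_genotypes builds markers x rils from per-marker strings; here we
    # want one RIL with this call sequence
    markers = [f"m{i}" for i in range(len(calls))]
    mat = codes.encode(np.array(list(calls))).reshape(-1, 1)
    genos = nr.RILGenotypes(
        family="fam", common_parent="P1", alt_parent="P2",
        markers=markers, rils=["r0"], calls=mat,
    )
    return genos, toy_map(markers)


class TestCallCrossovers:
    @pytest.mark.parametrize(
        "calls,k,expected",
        [
            ("AAABB", 2, 1),   # one clean phase change
            ("AABAA", 2, 0),   # lone discordant marker rejected
            ("AABAA", 1, 2),   # ...but counted twice by the single-marker rule
            ("AANBBB", 2, 1),  # missing call skipped
            ("ANBBB", 1, 1),
            ("AAAAA", 2, 0),
            ("ABABA", 2, 0),
            ("ABABA", 1, 4),
            ("BAAAA", 2, 0),   # terminal singleton treated as error
            ("AABBA", 2, 1),   # terminal short run dropped, one CO remains
        ],
    )
    def test_rule_on_toy_sequences(self, calls, k, expected):
        genos, gmap = _single_ril(calls)
        cos = call_crossovers(genos, gmap, k=k)
        assert len(cos) == expected

    def test_localization_and_midpoint(self):
        genos, gmap = _single_ril("AAABB")
        cos = call_crossovers(genos, gmap, k=2)
        row = cos.iloc[0]
        assert (row["left_marker"], row["right_marker"]) == ("m2", "m3")
        assert row["pos_cm"] == pytest.approx(2.5)
        assert (row["phase_from"], row["phase_to"]) == (0, 1)

    def test_missing_widens_flanking_interval(self):
        genos, gmap = _single_ril("AANBBB")
        row = call_crossovers(genos, gmap, k=2).iloc[0]
        assert (row["left_marker"], row["right_marker"]) == ("m1", "m3")
        assert row["pos_cm"] == pytest.approx(2.0)

    @given(st.text(alphabet="ABN", min_size=2, max_size=40))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_two_marker_count_never_exceeds_single(self, calls):
        genos, gmap = _single_ril(calls)
        assert len(call_crossovers(genos, gmap, k=2)) <= len(
            call_crossovers(genos, gmap, k=1)
        )

    def test_counts_and_positions_match_truth_on_clean_data(self, small_family):
        cos = call_crossovers(small_family["genos"], small_family["gmap"], k=1)
        truth_cos = small_family["truth_cos"]
        called = cos.groupby("ril").size()
        # positions within one marker interval (1 cM grid) of a truth junction
        merged = cos.merge(truth_cos, on=["ril", "chrom"], suffixes=("", "_t"))
        near = (merged["pos_cm"] - merged["pos_cm_t"]).abs() <= 1.0
        assert near.groupby([merged["ril"], merged["chrom"]]).any().all()


class TestCollapse:
    def test_identical_columns_share_bin(self):
        genos = toy_genotypes({"m1": "AABB", "m2": "AABB", "m3": "ABAB"})
        bins, delegates = collapse_redundant_markers(genos, min_overlap=2)
        assert bins["m1"] == bins["m2"] != bins["m3"]
        assert len(delegates) == 2

    def test_delegate_has_fewest_missing(self):
        genos = toy_genotypes({"m1": "AABBN", "m2": "AABBB", "m3": "NNABB"})
        bins, delegates = collapse_redundant_markers(genos, min_overlap=2)
        assert bins["m1"] == bins["m2"]
        assert "m2" in delegates  # fewer missing than m1

    def test_single_disagreement_splits(self):
        genos = toy_genotypes({"m1": "AABB", "m2": "AABA"})
        bins, _ = collapse_redundant_markers(genos, min_overlap=2)
        assert bins["m1"] != bins["m2"]

    def test_min_overlap_gate(self):
        # agree on their single shared RIL, but overlap below the gate
        genos = toy_genotypes({"m1": "ANNA", "m2": "ANNN"})
        bins, _ = collapse_redundant_markers(genos, min_overlap=2)
        assert bins["m1"] != bins["m2"]

    def test_co_calls_invariant_under_collapse(self):
        # complete (no-missing) mosaic matrix: redundancy collapse keeps all
        # genotype information, so delegate-only calling is lossless
        rng = np.random.default_rng(21)
        n_mark, n_ril = 60, 40
        phases = np.cumsum(rng.random((n_mark, n_ril)) < 0.04, axis=0) % 2
        markers = [f"m{i:03d}" for i in range(n_mark)]
        dup_of = {f"d{i:03d}": markers[i] for i in range(0, n_mark, 7)}
        all_markers = markers + list(dup_of)
        calls = np.vstack([phases] + [phases[[int(m[1:])]] for m in dup_of])
        genos = nr.RILGenotypes(
            family="fam", common_parent="P1", alt_parent="P2",
            markers=all_markers, rils=[f"r{i}" for i in range(n_ril)],
            calls=calls.astype(np.int8),
        )
        gmap = pd.DataFrame(
            {
                "marker": all_markers,
                "chrom": "c1",
                "cm": [float(int(m[1:])) for m in all_markers],
            }
        ).sort_values("cm", kind="stable")
        bins, delegates = collapse_redundant_markers(genos, min_overlap=5)
        for dup, orig in dup_of.items():
            assert bins[dup] == bins[orig]
        idx = [genos.markers.index(m) for m in delegates]
        sub = nr.RILGenotypes(
            family="fam", common_parent="P1", alt_parent="P2",
            markers=[genos.markers[i] for i in idx],
            rils=list(genos.rils), calls=genos.calls[idx, :],
        )
        # exact invariance holds for the position-based single-marker rule;
        # the k=2 rule counts run support, which bin-redundant markers add,
        # so it can differ at runs made entirely of redundant markers
        full = call_crossovers(genos, gmap, k=1).groupby("ril").size()
        dele = call_crossovers(sub, gmap, k=1).groupby("ril").size()
        pd.testing.assert_series_equal(
            full, dele.reindex(full.index).fillna(0).astype(full.dtype),
            check_names=False,
        )
        f2 = call_crossovers(genos, gmap, k=2).groupby("ril").size().reindex(full.index).fillna(0)
        d2 = call_crossovers(sub, gmap, k=2).groupby("ril").size().reindex(full.index).fillna(0)
        assert (f2 == d2).mean() > 0.85


@pytest.fixture()
def partition120():
    m = build_genome_model(
        [
            {"name": "c1", "length_cm": 120.0, "centromere_cm": 60.0, "n_markers": 5},
            {"name": "c2", "length_cm": 120.0, "centromere_cm": 60.0, "n_markers": 5},
        ]
    )
    return ArmPartition.from_model(m)


def _cos(rows):
    return pd.DataFrame(rows, columns=["ril", "chrom", "pos_cm"]).assign(
        left_marker="x", right_marker="y"
    )


class TestSummarize:
    def test_tco_conservation(self, partition120):
        cos = _cos(
            [("r1", "c1", 5.0), ("r1", "c1", 50.0), ("r1", "c1", 115.0),
             ("r1", "c2", 30.0), ("r1", "c2", 61.0)]
        )
        ph = summarize_phenotypes(cos, partition120)
        assert ph.loc["r1", "tco"] == 5
        assert ph.loc["r1", "tco"] == ph.loc["r1", "pco"] + ph.loc["r1", "dco"]
        assert ph.loc["r1", "tco"] == ph.loc["r1", "co_c1"] + ph.loc["r1", "co_c2"]

    def test_distal_vs_pericentromeric_assignment(self, partition120):
        # 90% of the arm length from the centromere is beyond the 2/3 boundary
        cos = _cos([("r1", "c1", 6.0), ("r1", "c1", 20.0), ("r1", "c1", 59.0)])
        ph = summarize_phenotypes(cos, partition120)
        assert ph.loc["r1", "dco"] == 1   # at 6 cM (distal third: < 20)
        assert ph.loc["r1", "pco"] == 2   # the exact boundary 20 and 59

    def test_breakpoint_outside_chromosome_rejected(self, partition120):
        with pytest.raises(ValueError, match="outside"):
            summarize_phenotypes(_cos([("r1", "c1", 130.0)]), partition120)

    def test_missing_threshold_exclusion(self, partition120):
        genos = toy_genotypes({f"m{i}": ("N" if i < 6 else "A") + "A" for i in range(10)})
        ph = summarize_phenotypes(_cos([]), partition120, genos=genos,
                                  missing_threshold=0.10)
        assert bool(ph.loc["r0", "excluded"]) is True
        assert bool(ph.loc["r1", "excluded"]) is False


class TestExcludeRegions:
    def test_whole_chromosome_exclusion_exact(self, partition120):
        cos = _cos([("r1", "c1", 10.0), ("r1", "c1", 50.0), ("r1", "c1", 110.0),
                    ("r1", "c2", 10.0), ("r1", "c2", 50.0)])
        ph = exclude_regions(cos, ["c1"], partition120)
        assert ph.loc["r1", "tco"] == 2
        full = summarize_phenotypes(cos, partition120)
        assert full.loc["r1", "tco"] - full.loc["r1", "co_c1"] == ph.loc["r1", "tco"]

    def test_no_exclusion_is_identity(self, partition120):
        cos = _cos([("r1", "c1", 10.0), ("r2", "c2", 61.0)])
        pd.testing.assert_frame_equal(
            exclude_regions(cos, [], partition120),
            summarize_phenotypes(cos, partition120),
        )

    def test_arm_region_exclusion(self, partition120):
        cos = _cos([("r1", "c2", 30.0), ("r1", "c2", 5.0), ("r1", "c1", 30.0)])
        ph = exclude_regions(cos, [("c2", "peri")], partition120)
        # drops only c2's pericentromeric CO at 30; keeps c2 distal and c1
        assert ph.loc["r1", "pco"] == 1 and ph.loc["r1", "dco"] == 1

    def test_unknown_chromosome_rejected(self, partition120):
        with pytest.raises(ValueError):
            exclude_regions(_cos([]), ["c9"], partition120)


class TestDistributionAndMaps:
    def test_histogram_mass_and_empty(self, small_model):
        cos = _cos([("r1", "chr1", 50.0)] * 7)
        hist, _ = breakpoint_distribution(cos, small_model, n_bins=10)
        assert hist.sum() == 7 and hist[5] == 7
        empty, frac = breakpoint_distribution(_cos([]), small_model)
        assert empty.sum() == 0 and np.isnan(frac)

    def test_uniform_intensity_fraction_distal(self, small_family):
        _hist, frac = breakpoint_distribution(
            small_family["truth_cos"], small_family["model"]
        )
        # uniform Poisson intensity puts one third of COs in the distal thirds
        assert frac == pytest.approx(1.0 / 3.0, abs=0.05)

    def test_map_summary_lengths_and_ratio(self):
        model = build_genome_model(
            [
                {"name": "c1", "length_cm": 120.0, "centromere_cm": 60.0,
                 "physical_mb": 600.0, "genome_class": "A", "n_markers": 13},
                {"name": "c2", "length_cm": 80.0, "centromere_cm": 40.0,
                 "physical_mb": 500.0, "genome_class": "B", "n_markers": 9},
            ]
        )
        s = map_summary(model.marker_table(), model)
        c1 = s[(s["scope"] == "chrom") & (s["name"] == "c1")].iloc[0]
        assert c1["length_cm"] == pytest.approx(120.0)
        assert c1["cm_per_mb"] == pytest.approx(0.2)
        ga = s[(s["scope"] == "genome") & (s["name"] == "A")].iloc[0]
        assert ga["length_cm"] == pytest.approx(120.0)
        tot = s[s["scope"] == "total"].iloc[0]
        assert tot["length_cm"] == pytest.approx(200.0)
        assert tot["n_markers"] == 22


class TestMapLengthEstimation:
    def test_full_density_estimate_close_to_truth(self, small_family):
        est = estimate_map_length(small_family["genos"], small_family["gmap"])
        assert est == pytest.approx(300.0, rel=0.15)

    def test_thinning_biases_length_downward(self, small_family):
        genos, gmap = small_family["genos"], small_family["gmap"]
        full = estimate_map_length(genos, gmap)
        thinned = thinning_experiment(genos, gmap, target_marker_count=60,
                                      n_reps=8, seed=9)
        assert thinned.attrs["mean_cm"] <= full
        again = thinning_experiment(genos, gmap, target_marker_count=60,
                                    n_reps=8, seed=9)
        pd.testing.assert_frame_equal(thinned, again)

    def test_target_exceeding_markers_rejected(self, small_family):
        with pytest.raises(ValueError):
            thinning_experiment(small_family["genos"], small_family["gmap"],
                                10_000, 2, seed=1)
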