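"""OTU filtering rules, per-fraction size spectra, the midpoint-weighted
diameter, vertical profiles and rank compositions, checked against
hand-enumerated tables and the simulator's filtration ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import picosize as ps
from picosize import sm
from picosize.fractions import DEFAULT_FRACTIONS, SizeFraction, parse_fractions

from conftest import make_otu_table


class TestFractions:
    def test_midpoints_of_study_design(self):
        np.testing.assert_allclose(
            [f.midpoint for f in DEFAULT_FRACTIONS], [0.4, 0.9, 1.6]
        )

    def test_parse_from_pore_sizes(self):
        fr = parse_fractions([0.2, 0.6, 1.2, 2.0])
        assert fr == DEFAULT_FRACTIONS
        with pytest.raises(ValueError):
            parse_fractions([0.6, 0.2])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SizeFraction(0.6, 0.2)


class TestFilterOtus:
    def test_hand_enumerated_survivors(self, toy_filter_case):
        table, tax, survivors = toy_filter_case
        filtered, log = ps.filter_otus(table, tax)
        assert set(filtered.index) == survivors
        assert log.low_abundance == ["B"]
        assert log.low_confidence == ["D"]
        assert log.excluded_lineage == ["E"]
        assert log.unannotated == ["F"]

    def test_threshold_is_strict_less_than(self, toy_filter_case):
        """Grand total 100 000 at 0.005%: 4 reads removed, 5 kept."""
        table, tax, _ = toy_filter_case
        filtered, _ = ps.filter_otus(table, tax)
        assert "B" not in filtered.index  # 4 < 5
        assert "C" in filtered.index      # 5 is not below 5

    def test_exclusion_beats_high_confidence(self, toy_filter_case):
        table, tax, _ = toy_filter_case
        _, log = ps.filter_otus(table, tax)
        assert "E" in log.excluded_lineage  # fungal despite confidence 0.99

    def test_idempotent(self, simulated_dataset):
        _, otu, tax, _ = simulated_dataset
        once, _ = ps.filter_otus(otu, tax)
        twice, log2 = ps.filter_otus(once, tax)
        pd.testing.assert_frame_equal(once, twice)
        assert not log2.removed

    def test_never_increases_counts(self, simulated_dataset):
        _, otu, tax, _ = simulated_dataset
        filtered, _ = ps.filter_otus(otu, tax)
        assert filtered.le(otu.loc[filtered.index]).all().all()

    def test_abundance_rule_is_per_marker(self):
        # 60 reads in 16S (total 1000) and 3 reads in 18S (total 30 000):
        # the 18S OTU fails its own marker's 0.5% bar even though it would
        # pass against the 16S total
        table = make_otu_table({
            "p16": {(5, "0.2-0.6", "16S"): 940},
            "q16": {(5, "0.2-0.6", "16S"): 60},
            "r18": {(5, "0.2-0.6", "18S"): 29_997},
            "s18": {(5, "0.2-0.6", "18S"): 3},
        })
        tax = pd.DataFrame(
            {"lineage": ["d__B;g__p", "d__B;g__q", "d__E;g__r", "d__E;g__s"],
             "confidence": [0.9] * 4,
             "group": ["p", "q", "r", "s"],
             "marker": ["16S", "16S", "18S", "18S"]},
            index=pd.Index(["p16", "q16", "r18", "s18"], name="otu_id"),
        )
        filtered, log = ps.filter_otus(table, tax, min_total_fraction=0.005)
        assert "s18" in log.low_abundance  # 3 < 0.005·30 000 = 150
        assert "q16" in filtered.index     # 60 ≥ 0.005·1000 = 5

    def test_empty_table_warns(self):
        empty = make_otu_table({}) if False else pd.DataFrame()
        with pytest.warns(UserWarning, match="empty"):
            out, _ = ps.filter_otus(empty, pd.DataFrame())
        assert out.empty


class TestFractionProportions:
    def test_simple_shares(self):
        table = make_otu_table({
            "a": {(5, "0.2-0.6", "16S"): 600,
                  (5, "0.6-1.2", "16S"): 300,
                  (5, "1.2-2", "16S"): 100},
        })
        tax = pd.DataFrame(
            {"lineage": ["d__B;g__a"], "confidence": [0.9],
             "group": ["a"], "marker": ["16S"]},
            index=pd.Index(["a"], name="otu_id"),
        )
        prop = ps.fraction_proportions(table, tax, "a", normalize="raw")
        np.testing.assert_allclose(prop.to_numpy(), [0.6, 0.3, 0.1])
        assert prop.sum() == pytest.approx(1.0)

    def test_single_fraction_group(self):
        table = make_otu_table({
            "a": {(5, "0.2-0.6", "16S"): 42},
            "b": {(5, "0.6-1.2", "16S"): 7},
        })
        tax = pd.DataFrame(
            {"lineage": ["x", "y"], "confidence": [0.9, 0.9],
             "group": ["a", "b"], "marker": ["16S", "16S"]},
            index=pd.Index(["a", "b"], name="otu_id"),
        )
        prop = ps.fraction_proportions(table, tax, "a", normalize="raw")
        np.testing.assert_allclose(prop.to_numpy(), [1.0, 0.0, 0.0])

    def test_absent_group_flagged(self, toy_filter_case):
        table, tax, _ = toy_filter_case
        with pytest.raises(ValueError, match="absent"):
            ps.fraction_proportions(table, tax, "no_such_group")

    def test_matches_simulator_capture_proportions(self):
        """With ideal retention and a dominant fraction-uniform
        background in the library, a focal taxon's read proportions
        track its true capture split within sampling noise."""
        from picosize.synthetic import (
            DEFAULT_DEPTHS_M, FluorParams, PICOEUKARYOTE_TAXON, TaxonSpec,
            taxonomy_table,
        )
        fluor = FluorParams(np.log(5.0), np.log(500.0))
        focal = TaxonSpec(
            "focal", PICOEUKARYOTE_TAXON, "18S", 0.9, 0.2,
            (1.0,) * 6, fluor, lineage="d__E;g__focal",
        )
        background = TaxonSpec(
            "bkg", "background", "18S", 1.0, 0.3, (50.0,) * 6, fluor,
            debris=True, lineage="d__E;p__Metazoa;g__bkg",
        )
        truth = ps.CommunityTruth(taxa=(focal, background), seed=21)
        res = ps.simulate_fractionation(
            truth, 113, 300_000, ps.RetentionModel(ideal=True), seed=21
        )
        read_depth = 300_000
        otu = ps.simulate_reads(res.weights, read_depth, truth, seed=22,
                                depth=113)
        prop = ps.fraction_proportions(otu, taxonomy_table(truth), "focal",
                                       normalize="raw")
        w = res.weights.loc["focal"]
        true_prop = (w / w.sum()).to_numpy()
        n_focal = otu.loc["focal"].sum()
        for est, p in zip(prop.to_numpy(), true_prop):
            sd = np.sqrt(max(p * (1 - p), 1e-12) / n_focal)
            assert est == pytest.approx(p, abs=3 * sd + 0.01)


class TestDiameterSm:
    @pytest.mark.parametrize(
        "props,expected",
        [
            ((0.5986, 0.2793, 0.1221), 0.686),   # small-cell dominated
            ((0.3146, 0.2932, 0.3922), 1.017),   # bimodal-ish
            ((0.1471, 0.3241, 0.5288), 1.197),   # large-cell dominated
            ((1.0, 0.0, 0.0), 0.4),
            ((0.0, 0.0, 1.0), 1.6),
        ],
    )
    def test_midpoint_weighting(self, props, expected):
        assert ps.estimate_diameter_sm(props) == pytest.approx(expected, abs=5e-4)

    def test_rejects_bad_proportions(self):
        with pytest.raises(ValueError, match="sum"):
            ps.estimate_diameter_sm((0.5, 0.2, 0.1))
        with pytest.raises(ValueError):
            ps.estimate_diameter_sm((0.5, 0.5))

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3)
           .filter(lambda w: sum(w) > 1e-6))
    @settings(deadline=None, max_examples=100)
    def test_bounded_by_extreme_midpoints(self, weights):
        p = np.array(weights) / sum(weights)
        d = ps.estimate_diameter_sm(p)
        assert 0.4 - 1e-9 <= d <= 1.6 + 1e-9

    def test_strictly_increasing_as_mass_moves_up(self):
        d1 = ps.estimate_diameter_sm((0.5, 0.3, 0.2))
        d2 = ps.estimate_diameter_sm((0.4, 0.3, 0.3))
        assert d2 > d1

    def test_expected_value_equals_discretized_truth_under_ideal_retention(self):
        """Under step retention and no fragility the SM estimator is, in
        expectation, the fraction-midpoint discretization of the size
        distribution (lognormal CDF oracle)."""
        from scipy.stats import lognorm
        median, log_sd = 0.9, 0.2
        dist = lognorm(s=log_sd, scale=median)
        mass = np.array([
            dist.cdf(f.upper) - dist.cdf(f.lower) for f in DEFAULT_FRACTIONS
        ])
        oracle = float(np.array([f.midpoint for f in DEFAULT_FRACTIONS])
                       @ (mass / mass.sum()))

        from test_synthetic import single_taxon_truth
        truth = single_taxon_truth(median, log_sd=log_sd)
        res = ps.simulate_fractionation(
            truth, 5, 200_000, ps.RetentionModel(ideal=True), seed=23
        )
        w = res.weights.loc["only"]
        est = ps.estimate_diameter_sm((w / w.sum()).to_numpy())
        assert est == pytest.approx(oracle, abs=0.01)


class TestVerticalProfiles:
    def _tax(self, names, marker="16S"):
        return pd.DataFrame(
            {"lineage": [f"d__B;g__{n}" for n in names],
             "confidence": [0.9] * len(names),
             "group": list(names), "marker": [marker] * len(names)},
            index=pd.Index(list(names), name="otu_id"),
        )

    def test_argmax_depth_reported(self):
        table = make_otu_table({
            "a": {(5, "0.2-0.6", "16S"): 1, (113, "0.2-0.6", "16S"): 50},
        })
        prof = ps.vertical_profiles(table, self._tax(["a"]), ["a"],
                                    normalize="raw")
        assert prof.attrs["argmax_depth"]["a"] == 113.0

    def test_proportional_groups_have_identical_shapes(self):
        table = make_otu_table({
            "a": {(5, "0.2-0.6", "16S"): 10, (113, "0.2-0.6", "16S"): 30},
            "b": {(5, "0.2-0.6", "16S"): 100, (113, "0.2-0.6", "16S"): 300},
        })
        prof = ps.vertical_profiles(table, self._tax(["a", "b"]), ["a", "b"],
                                    normalize="raw")
        shape_a = prof.loc["a"] / prof.loc["a"].sum()
        shape_b = prof.loc["b"] / prof.loc["b"].sum()
        pd.testing.assert_series_equal(shape_a, shape_b, check_names=False)

    def test_dcm_peaked_taxon_recovers_configured_maximum(self, simulated_dataset):
        truth, otu, tax, _ = simulated_dataset
        filtered, _ = ps.filter_otus(otu, tax)
        prof = ps.vertical_profiles(filtered, tax, ["Pelagomonas"],
                                    normalize="raw")
        assert prof.attrs["argmax_depth"]["Pelagomonas"] == 113.0


class TestRelativeAbundance:
    def test_single_class_is_everything(self):
        table = make_otu_table({"a": {(5, "0.2-0.6", "18S"): 10}})
        tax = pd.DataFrame(
            {"lineage": ["d__E;p__H;c__Prymnesiophyceae;g__Chry"],
             "confidence": [0.9], "group": ["Chry"], "marker": ["18S"]},
            index=pd.Index(["a"], name="otu_id"),
        )
        comp = ps.relative_abundance(table, tax, rank="class")
        assert comp["Prymnesiophyceae"] == pytest.approx(1.0)

    def test_known_percentage_split(self):
        table = make_otu_table({
            "a": {(5, "0.2-0.6", "18S"): 380},
            "b": {(5, "0.2-0.6", "18S"): 220},
            "c": {(5, "0.2-0.6", "18S"): 400},
        })
        tax = pd.DataFrame(
            {"lineage": ["d__E;c__X;g__a", "d__E;c__Y;g__b", "d__E;c__Z;g__c"],
             "confidence": [0.9] * 3, "group": list("abc"),
             "marker": ["18S"] * 3},
            index=pd.Index(list("abc"), name="otu_id"),
        )
        comp = ps.relative_abundance(table, tax, rank="class", normalize="raw")
        assert comp["Z"] == pytest.approx(0.40)
        assert comp["X"] == pytest.approx(0.38)
        assert comp["Y"] == pytest.approx(0.22)
        assert comp.sum() == pytest.approx(1.0)

    def test_genus_collapse_matches_hand_sums(self):
        counts = {f"o{i}": {(5, "0.2-0.6", "18S"): 10 * (i + 1)} for i in range(10)}
        table = make_otu_table(counts)
        genus = ["g1"] * 4 + ["g2"] * 6
        tax = pd.DataFrame(
            {"lineage": [f"d__E;g__{g}" for g in genus],
             "confidence": [0.9] * 10, "group": genus, "marker": ["18S"] * 10},
            index=pd.Index(list(counts), name="otu_id"),
        )
        comp = ps.relative_abundance(table, tax, rank="genus", normalize="raw")
        # hand sums: g1 = 10+20+30+40 = 100; g2 = 50+...+100 = 450
        assert comp["g1"] == pytest.approx(100 / 550)
        assert comp["g2"] == pytest.approx(450 / 550)
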