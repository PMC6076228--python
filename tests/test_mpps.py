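"""The ensemble classifier: category mapping, weights, trio scoring and the
iterative agreement protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mendiag import synthdata
from mendiag.predictors import (
    BENIGN,
    DAMAGING,
    FUNCTIONAL_TOOLS,
    POSSIBLY_BENIGN,
    POSSIBLY_DAMAGING,
    TOOLS,
    UNCLASSIFIED,
    category_band_midpoint,
    category_points,
    map_raw_to_category,
)
from mendiag.mpps import (
    GENOME_WIDE,
    MppsClassifier,
    RegionWeightTable,
    WeightRow,
    classify_variant,
    conservation_bonus,
    fit_region_weights,
    predict_batch,
    select_trios,
    trio_score,
    weighted_trio_score,
)
from mendiag.variants import VariantRecord

CATEGORY_VALUES = [DAMAGING, POSSIBLY_DAMAGING, UNCLASSIFIED, POSSIBLY_BENIGN, BENIGN]


class TestCategoryMapping:
    @pytest.mark.parametrize(
        "tool,raw,expected",
        [
            ("SIFT", None, UNCLASSIFIED),
            ("SIFT", 0.01, DAMAGING),
            ("SIFT", 0.97, BENIGN),
            ("SIFT", 0.2, POSSIBLY_DAMAGING),
            ("SIFT", 0.7, POSSIBLY_BENIGN),
            ("Polyphen2_HDIV", 0.99, DAMAGING),
            ("Polyphen2_HDIV", 0.1, BENIGN),
            ("CADD", 30.0, DAMAGING),
            ("CADD", 5.0, BENIGN),
            ("CADD", 17.0, POSSIBLY_DAMAGING),
        ],
    )
    def test_default_thresholds(self, tool, raw, expected):
        assert map_raw_to_category(tool, raw) == expected

    def test_unknown_tool_is_error(self):
        with pytest.raises(ValueError):
            map_raw_to_category("NotATool", 0.5)

    def test_band_midpoints_invert_the_mapping(self):
        """Synthetic raw scores placed at band midpoints map back to the
        category they were generated from, for every tool and category."""
        for tool in TOOLS:
            for cat in (DAMAGING, POSSIBLY_DAMAGING, POSSIBLY_BENIGN, BENIGN):
                raw = category_band_midpoint(tool, cat)
                assert map_raw_to_category(tool, raw) == cat, (tool, cat)

    @pytest.mark.parametrize(
        "category,points",
        [
            (DAMAGING, 10),
            (POSSIBLY_DAMAGING, 5),
            (UNCLASSIFIED, 0),
            (POSSIBLY_BENIGN, -5),
            (BENIGN, -10),
        ],
    )
    def test_category_points(self, category, points):
        assert category_points(category) == points


class TestTrioScore:
    def test_hand_arithmetic_example(self):
        # weights (1.0, 0.5, 0.5), categories (damaging, benign, unclassified)
        # -> (10*1 + (-10)*0.5 + 0*0.5) / 2.0 = 2.5
        assert weighted_trio_score([10, -10, 0], [1.0, 0.5, 0.5]) == pytest.approx(2.5)

    def test_unanimous_extremes(self):
        assert weighted_trio_score([10, 10, 10], [0.3, 0.9, 0.5]) == pytest.approx(10)
        assert weighted_trio_score([-10, -10, -10], [1, 1, 1]) == pytest.approx(-10)

    def test_zero_weights_score_zero(self):
        assert weighted_trio_score([10, 10, 10], [0, 0, 0]) == 0.0

    @settings(max_examples=300, derandomize=True)
    @given(
        pts=st.lists(st.sampled_from([-10, -5, 0, 5, 10]), min_size=3, max_size=3),
        ws=st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=3),
    )
    def test_matches_brute_force_weighted_mean(self, pts, ws):
        expected = 0.0 if sum(ws) == 0 else sum(w * p for w, p in zip(ws, pts)) / sum(ws)
        got = weighted_trio_score(pts, ws)
        assert abs(got - expected) <= 1e-12
        assert -10.0 - 1e-12 <= got <= 10.0 + 1e-12

    @settings(max_examples=200, derandomize=True)
    @given(
        pts=st.lists(st.sampled_from([-10, -5, 0, 5, 10]), min_size=3, max_size=3),
        ws=st.lists(st.floats(0.01, 1, allow_nan=False), min_size=3, max_size=3),
        which=st.integers(0, 2),
    )
    def test_monotone_in_member_category(self, pts, ws, which):
        """Upgrading one trio member toward damaging never lowers the score."""
        upgraded = list(pts)
        if upgraded[which] < 10:
            upgraded[which] += 5
        assert weighted_trio_score(upgraded, ws) >= weighted_trio_score(pts, ws) - 1e-12

    def test_trio_score_via_profile_and_weights_table(self):
        table = RegionWeightTable(bin_size=10)
        for tool, w in (("SIFT", 1.0), ("CADD", 0.5), ("DANN", 0.5)):
            table.set(GENOME_WIDE, tool, WeightRow(w, w, 10, 10))
        profile = {"SIFT": 0.01, "CADD": 5.0}  # damaging, benign, DANN absent
        s = trio_score(profile, ("SIFT", "CADD", "DANN"), table, GENOME_WIDE, "dmg")
        assert s == pytest.approx(2.5)


class TestWeightFitting:
    def _records_in_bin(self, n, chrom="1", start=1_000_000):
        return [
            VariantRecord(chrom, start + i, "A", "G", "SNV", consequence="missense")
            for i in range(n)
        ]

    def test_correct_fraction_is_counted(self):
        """A tool calling 9 of 10 pathogenic variants damaging gets w_dmg 0.9."""
        recs = self._records_in_bin(20)
        truth = {}
        for i, r in enumerate(recs):
            pathogenic = i < 10
            truth[r.key] = "pathogenic" if pathogenic else "neutral"
            if pathogenic:
                r.tool_scores = {"SIFT": 0.01 if i < 9 else 0.99}
            else:
                r.tool_scores = {"SIFT": 0.99}
        w = fit_region_weights(truth, recs, bin_size=10_000_000, min_n=5)
        region = w.region_of("1", recs[0].pos)
        assert w.weight(region, "SIFT", "dmg") == pytest.approx(0.9)
        assert w.weight(region, "SIFT", "ben") == pytest.approx(1.0)

    def test_small_bins_inherit_genome_wide_fallback(self):
        recs = self._records_in_bin(20)
        truth = {r.key: ("pathogenic" if i < 10 else "neutral") for i, r in enumerate(recs)}
        for i, r in enumerate(recs):
            r.tool_scores = {"SIFT": 0.01 if i < 10 else 0.99}
        w = fit_region_weights(truth, recs, min_n=50)  # 10 per class < min_n
        region = w.region_of("1", recs[0].pos)
        assert (region, "SIFT") not in w.rows
        assert (GENOME_WIDE, "SIFT") in w.rows
        assert w.weight(region, "SIFT", "dmg") == pytest.approx(1.0)

    def test_empty_truth_is_error(self):
        with pytest.raises(ValueError):
            fit_region_weights({}, [])

    def test_single_class_truth_warns_and_uses_prior(self):
        recs = self._records_in_bin(10)
        truth = {r.key: "pathogenic" for r in recs}
        for r in recs:
            r.tool_scores = {"SIFT": 0.01}
        with pytest.warns(UserWarning, match="neutral"):
            w = fit_region_weights(truth, recs, min_n=5)
        assert w.weight(GENOME_WIDE, "SIFT", "ben") == pytest.approx(0.5)

    def test_deterministic_given_seed(self, small_benchmark):
        truth, profiled, _, _ = small_benchmark
        w1 = fit_region_weights(truth, profiled, seed=5, subsample=0.8)
        w2 = fit_region_weights(truth, profiled, seed=5, subsample=0.8)
        assert {k: vars(v) for k, v in w1.rows.items()} == {
            k: vars(v) for k, v in w2.rows.items()
        }

    def test_tsv_round_trip(self, small_benchmark, tmp_path):
        _, _, _, weights = small_benchmark
        p = tmp_path / "w.tsv"
        weights.to_tsv(str(p))
        back = RegionWeightTable.from_tsv(str(p))
        assert back.bin_size == weights.bin_size
        for key, row in weights.rows.items():
            assert vars(back.rows[key]) == pytest.approx(vars(row), abs=1e-6)


class TestTrioSelection:
    def _table(self, dmg_weights):
        t = RegionWeightTable()
        for tool in FUNCTIONAL_TOOLS:
            w = dmg_weights.get(tool, 0.5)
            t.set(GENOME_WIDE, tool, WeightRow(w, 1.0 - w, 100, 100))
        return t

    def test_round1_takes_top3_each_side(self):
        t = self._table({"SIFT": 0.99, "CADD": 0.98, "DANN": 0.97, "LRT": 0.01, "VEST3": 0.02, "MetaLR": 0.03})
        sel = select_trios(t, GENOME_WIDE, 1)
        assert sel.dmg_tools == ("SIFT", "CADD", "DANN")
        # benign weights are 1 - dmg: worst dmg tools lead the benign side
        assert sel.ben_tools == ("LRT", "VEST3", "MetaLR")

    def test_ties_break_alphabetically(self):
        t = self._table({})  # every tool at 0.5
        sel = select_trios(t, GENOME_WIDE, 1)
        assert sel.dmg_tools == tuple(sorted(FUNCTIONAL_TOOLS))[:3]

    def test_round2_takes_ranks_4_to_6(self):
        t = self._table({})
        r1 = select_trios(t, GENOME_WIDE, 1)
        r2 = select_trios(t, GENOME_WIDE, 2)
        ranked = sorted(FUNCTIONAL_TOOLS)
        assert r2.dmg_tools == tuple(ranked[3:6])
        assert not set(r1.dmg_tools) & set(r2.dmg_tools)

    def test_round_beyond_ranked_list_is_error(self):
        t = self._table({})
        with pytest.raises(ValueError):
            select_trios(t, GENOME_WIDE, 6)


class TestConservationBonus:
    def test_conserved_adds_one(self):
        assert conservation_bonus(5.0, gerp=4.0, phylop=3.0) == 6.0

    def test_not_conserved_is_noop(self):
        assert conservation_bonus(5.0, gerp=1.0, phylop=3.0) == 5.0

    def test_absent_score_means_not_conserved(self):
        assert conservation_bonus(5.0, gerp=None, phylop=3.0) == 5.0

    def test_clamped_at_ten(self):
        assert conservation_bonus(10.0, gerp=4.0, phylop=3.0) == 10.0


class TestClassifyVariant:
    def _uniform_weights(self):
        t = RegionWeightTable()
        for tool in TOOLS:
            t.set(GENOME_WIDE, tool, WeightRow(0.9, 0.9, 100, 100))
        return t

    def test_unanimously_damaging_agrees_in_round_one(self):
        profile = {t: category_band_midpoint(t, DAMAGING) for t in FUNCTIONAL_TOOLS}
        res = classify_variant(profile, self._uniform_weights())
        assert res.classification == DAMAGING
        assert res.round_used == 1
        assert not res.mis_classified

    def test_unanimously_benign_classifies_benign(self):
        profile = {t: category_band_midpoint(t, BENIGN) for t in FUNCTIONAL_TOOLS}
        res = classify_variant(profile, self._uniform_weights())
        assert res.classification == BENIGN
        assert res.score_dmg <= -1 and res.score_ben <= -1

    def test_no_round_agrees_flags_misclassified(self):
        """Every rank triple scoring (10, -10, 0) averages to 0 on both
        sides, so no round reaches the agreement margin: the variant is
        flagged mis-classified but still classified (fall-back rule)."""
        weights = self._uniform_weights()
        ranked = sorted(FUNCTIONAL_TOOLS)  # equal weights tie-break by name
        pattern = (DAMAGING, BENIGN, UNCLASSIFIED)
        profile = {}
        for i, tool in enumerate(ranked):
            cat = pattern[i % 3]
            if cat is not UNCLASSIFIED:
                profile[tool] = category_band_midpoint(tool, cat)
        res = classify_variant(profile, weights)
        assert res.mis_classified
        assert res.round_used == 5
        assert res.classification in (DAMAGING, BENIGN)
        assert res.score_dmg == pytest.approx(0.0)

    def test_all_tools_absent_yields_misclassified_fallback(self):
        res = classify_variant({}, self._uniform_weights())
        assert res.mis_classified
        assert res.classification in (DAMAGING, BENIGN)
        assert res.score_dmg == 0.0 and res.score_ben == 0.0

    def test_conservation_flag_reported(self):
        profile = {t: category_band_midpoint(t, DAMAGING) for t in FUNCTIONAL_TOOLS}
        profile["GERP++"] = 5.0
        profile["phyloP100way"] = 4.0
        res = classify_variant(profile, self._uniform_weights())
        assert res.conserved


class TestPredictBatch:
    def test_one_result_per_variant_in_order(self, small_benchmark):
        truth, profiled, _, weights = small_benchmark
        results = predict_batch(profiled, weights)
        assert len(results) == len(profiled)

    def test_variant_with_no_scores_still_classified(self, small_benchmark):
        _, profiled, _, weights = small_benchmark
        bare = VariantRecord("1", 42, "A", "G", "SNV")
        results = predict_batch([bare], weights)
        assert len(results) == 1 and results[0].classification in (DAMAGING, BENIGN)

    def test_empty_batch(self, small_benchmark):
        _, _, _, weights = small_benchmark
        assert predict_batch([], weights) == []


def test_classifier_wrapper_fit_predict(small_benchmark):
    truth, profiled, _, _ = small_benchmark
    clf = MppsClassifier(min_n=50, seed=0)
    results = clf.fit(truth, profiled).predict(profiled)
    assert len(results) == len(profiled)
    with pytest.raises(RuntimeError):
        MppsClassifier().predict(profiled)
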