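"""Unit and property tests for the Remuzzi scoring engine."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nephromet import (
    ArteryMeasurement,
    SlideMeasurement,
    ThresholdConfig,
    assess_adequacy,
    band_score,
    decide_continuous,
    decide_total,
    is_scorable_artery,
    score_arteriosclerosis,
    score_glomerulosclerosis,
    score_ifta,
    score_slide,
    wall_lumen_ratio,
)
from nephromet.errors import ConfigurationError, InputError


def brute_band(value, bands):
    """Independent oracle: linear scan over left-closed cut-points."""
    score = 0
    for b in bands:
        if value >= b:
            score += 1
    return score


def make_artery(ratio_pct, artery_id="a1", layers=2, lumen=100.0):
    w = ratio_pct / 200 * lumen     # each wall; (a + b) / lumen = ratio
    return ArteryMeasurement(artery_id, lumen_diameter=lumen, wall_thickness_a=w,
                             wall_thickness_b=w, smooth_muscle_layers=layers)


def make_slide(n_glomeruli=30, n_sclerosed=0, ifta_pct=0.0, ta_pct=None,
               arteries=(), **kw):
    defaults = dict(slide_id="s1", biopsy_id="b1", donor_id="D01",
                    kidney_side="left", technique="core", stain="HE",
                    width=1.0, depth=10.0, cortex_area=9.0)
    defaults.update(kw)
    return SlideMeasurement(n_glomeruli=n_glomeruli, n_sclerosed=n_sclerosed,
                            ifta_pct=ifta_pct, tubular_atrophy_pct=ta_pct,
                            arteries=tuple(arteries), **defaults)


class TestBandScore:
    @pytest.mark.parametrize("value,expected", [
        (0, 0), (49.9, 0), (50.0, 1), (50.1, 1), (79.9, 1),
        (80.0, 2), (100, 2), (119.9, 2), (120.0, 3), (500, 3),
    ])
    def test_arterial_bands(self, value, expected):
        assert band_score(value, (50, 80, 120)) == expected

    def test_matches_linear_scan_oracle(self, rng):
        """10,000 random values per band configuration equal a brute scan."""
        for _ in range(5):
            cuts = np.sort(rng.uniform(0, 120, 3))
            while len(np.unique(cuts)) < 3:
                cuts = np.sort(rng.uniform(0, 120, 3))
            values = rng.uniform(0, 200, 10_000)
            got = [band_score(v, cuts) for v in values]
            want = [brute_band(v, cuts) for v in values]
            assert got == want

    def test_rejects_non_ascending_bands(self):
        with pytest.raises(ConfigurationError):
            band_score(10, (80, 50, 120))
        with pytest.raises(ConfigurationError):
            band_score(10, (50, 50, 120))

    def test_rejects_negative_value(self):
        with pytest.raises(InputError):
            band_score(-1, (50, 80, 120))


class TestGlomerulosclerosis:
    def test_no_sclerosis_scores_zero(self):
        assert score_glomerulosclerosis(40, 0) == 0

    @pytest.mark.parametrize("n,k", [(20, 2), (10, 6), (5, 1), (3, 2)])
    def test_equals_band_lookup_on_percentage(self, n, k, thresholds):
        expected = band_score(100 * k / n, thresholds.gs_bands)
        assert score_glomerulosclerosis(n, k, thresholds) == expected

    def test_exact_rational_boundary(self, thresholds):
        # 1/5 = 20% lands exactly on the 20% cut-point: higher band
        assert score_glomerulosclerosis(5, 1, thresholds) == 2
        # just below: 19.9...% via 199/1000
        assert score_glomerulosclerosis(1000, 199, thresholds) == 1

    def test_no_glomeruli_is_unscorable_not_zero(self):
        assert score_glomerulosclerosis(0, 0) is None

    def test_invalid_counts(self):
        with pytest.raises(InputError):
            score_glomerulosclerosis(5, 6)


class TestIfta:
    @pytest.mark.parametrize("pct,expected", [
        (0.0, (0, 0)), (4.9, (0, 0)), (4.999999, (0, 0)),
        (5.0, (1, 1)), (19.9, (1, 1)), (20.0, (2, 2)), (50.0, (3, 3)),
    ])
    def test_censor_and_bands(self, pct, expected):
        assert score_ifta(pct) == expected

    def test_censored_region_boundary_scan(self, thresholds):
        """Every value strictly below the censor scores 0; at/above it bands."""
        for pct in np.arange(0, 10, 0.1):
            s_if, s_ta = score_ifta(float(pct), thresholds)
            if pct < thresholds.ifta_censor - 1e-9:
                assert (s_if, s_ta) == (0, 0)
            else:
                assert s_if == band_score(pct, thresholds.if_bands)

    def test_separate_tubular_atrophy_entry(self, thresholds):
        s_if, s_ta = score_ifta(30.0, thresholds, tubular_atrophy_pct=10.0)
        assert (s_if, s_ta) == (2, 1)
        # the censor applies to each component independently
        assert score_ifta(30.0, thresholds, tubular_atrophy_pct=3.0) == (2, 0)

    def test_out_of_range(self):
        with pytest.raises(InputError):
            score_ifta(101.0)


class TestWallLumenRatio:
    def test_symmetric_geometry(self):
        a = ArteryMeasurement("a", 20, 10, 10)
        assert wall_lumen_ratio(a) == pytest.approx(100.0)

    def test_hand_arithmetic(self):
        # (8 + 12) / 25 = 80 %
        a = ArteryMeasurement("a", 25, 8, 12)
        assert wall_lumen_ratio(a) == pytest.approx(80.0)

    def test_minor_axis_correction(self):
        # obliquely cut vessel: lumen measured along the 40 um major axis,
        # true (minor-axis) diameter 20 um
        a = ArteryMeasurement("a", 40, 10, 10, minor_axis=20, major_axis=40)
        assert wall_lumen_ratio(a) == pytest.approx(100.0)
        assert wall_lumen_ratio(a, use_minor_axis_correction=False) == pytest.approx(50.0)

    def test_wall_swap_symmetry(self):
        a = ArteryMeasurement("a", 25, 8, 12)
        b = ArteryMeasurement("a", 25, 12, 8)
        assert wall_lumen_ratio(a) == wall_lumen_ratio(b)


class TestScorableArtery:
    @pytest.mark.parametrize("layers,diameter,expected", [
        (2, 100.0, True),    # layer criterion alone
        (1, 131.0, True),    # diameter criterion alone, strict >
        (1, 130.0, False),
        (0, None, False),
        (3, None, True),
    ])
    def test_criteria(self, layers, diameter, expected):
        a = ArteryMeasurement("a", 20, 5, 5, smooth_muscle_layers=layers,
                              overall_diameter=diameter)
        assert is_scorable_artery(a) is expected


class TestArteriosclerosis:
    def test_worst_artery_rule(self):
        arts = [make_artery(40, "a1"), make_artery(130, "a2")]
        score, worst = score_arteriosclerosis(arts)
        assert score == 3 and worst == "a2"

    def test_no_arteries_unscorable(self):
        assert score_arteriosclerosis([]) == (None, None)

    def test_unscorable_arteries_ignored(self):
        arts = [make_artery(130, "a1", layers=0)]
        assert score_arteriosclerosis(arts) == (None, None)

    def test_single_artery_mid_band(self):
        score, worst = score_arteriosclerosis([make_artery(60, "a1")])
        assert score == 1 and worst == "a1"

    def test_tie_breaks_to_lower_id(self):
        arts = [make_artery(90, "b"), make_artery(90, "a")]
        assert score_arteriosclerosis(arts)[1] == "a"

    def test_wall_swap_never_changes_score(self, rng):
        for _ in range(50):
            lumen = rng.uniform(20, 200)
            wa, wb = rng.uniform(1, 80, 2)
            a1 = ArteryMeasurement("a", lumen, wa, wb, smooth_muscle_layers=2)
            a2 = ArteryMeasurement("a", lumen, wb, wa, smooth_muscle_layers=2)
            assert score_arteriosclerosis([a1]) == score_arteriosclerosis([a2])


class TestAdequacy:
    @pytest.mark.parametrize("n_glom,n_art,expected", [
        (25, 1, (True, True, True)),
        (24, 1, (False, True, False)),
        (30, 0, (True, False, False)),
        (24, 0, (False, False, False)),
        (26, 2, (True, True, True)),
    ])
    def test_boundaries(self, n_glom, n_art, expected):
        arts = [make_artery(40, f"a{i}") for i in range(n_art)]
        s = make_slide(n_glomeruli=n_glom, arteries=arts)
        assert assess_adequacy(s) == expected

    def test_unscorable_arteries_do_not_count(self):
        s = make_slide(n_glomeruli=30,
                       arteries=[make_artery(40, "a1", layers=1)])
        assert assess_adequacy(s) == (True, False, False)


class TestDecisions:
    @pytest.mark.parametrize("total,expected", [
        (0, "single"), (1, "single"), (4, "single"),
        (5, "dual"), (6, "dual"), (7, "discard"), (12, "discard"),
    ])
    def test_decide_total(self, total, expected):
        assert decide_total(total) == expected

    @pytest.mark.parametrize("mean,expected", [
        (0.0, "single"), (4.0, "single"), (4.3, "dual"), (6.0, "dual"),
        (6.5, "dual"), (6.999, "dual"), (7.0, "discard"), (12.0, "discard"),
    ])
    def test_decide_continuous(self, mean, expected):
        assert decide_continuous(mean) == expected

    def test_agreement_on_all_integer_totals(self):
        for t in range(13):
            assert decide_total(t) == decide_continuous(float(t))

    def test_out_of_range(self):
        with pytest.raises(InputError):
            decide_total(13)
        with pytest.raises(InputError):
            decide_continuous(12.5)
        with pytest.raises(InputError):
            decide_total(3.5)


class TestScoreSlide:
    def test_healthy_slide(self):
        s = make_slide(n_glomeruli=40, arteries=[make_artery(30, "a1")])
        r = score_slide(s)
        assert (r.score_gs, r.score_if, r.score_ta, r.score_art) == (0, 0, 0, 0)
        assert r.total == 0 and r.decision == "single"
        assert r.adequate and r.glomerular_adequate and r.arterial_adequate

    def test_component_sum_and_decision(self):
        # components (1, 1, 1, 1) -> total 4 -> single
        s = make_slide(n_glomeruli=40, n_sclerosed=4, ifta_pct=10.0,
                       arteries=[make_artery(60, "a1")])
        r = score_slide(s)
        assert (r.score_gs, r.score_if, r.score_ta, r.score_art) == (1, 1, 1, 1)
        assert r.total == 4 and r.decision == "single"

    def test_discard_composition(self):
        # components (2, 2, 2, 1) -> total 7 -> discard
        s = make_slide(n_glomeruli=40, n_sclerosed=10, ifta_pct=25.0,
                       arteries=[make_artery(60, "a1")])
        r = score_slide(s)
        assert (r.score_gs, r.score_if, r.score_ta, r.score_art) == (2, 2, 2, 1)
        assert r.total == 7 and r.decision == "discard"

    def test_unscorable_artery_suppresses_total(self):
        s = make_slide(n_glomeruli=40, n_sclerosed=4, ifta_pct=10.0)
        r = score_slide(s)
        assert r.score_art is None and r.total is None and r.decision is None
        assert r.score_gs == 1          # other components still reported
        assert not r.arterial_adequate

    def test_inadequate_slides_still_scored(self):
        s = make_slide(n_glomeruli=10, n_sclerosed=1,
                       arteries=[make_artery(60, "a1")])
        r = score_slide(s)
        assert not r.adequate and r.total is not None

    def test_ta_imputation_flagged(self):
        r1 = score_slide(make_slide(ifta_pct=30.0, arteries=[make_artery(30, "a")]))
        r2 = score_slide(make_slide(ifta_pct=30.0, ta_pct=30.0,
                                    arteries=[make_artery(30, "a")]))
        assert r1.ta_imputed and not r2.ta_imputed
        assert r1.score_ta == r2.score_ta == 2

    def test_pure_function(self):
        s = make_slide(n_glomeruli=33, n_sclerosed=7, ifta_pct=12.5,
                       arteries=[make_artery(85, "a1"), make_artery(55, "a2")])
        assert score_slide(s) == score_slide(s)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n_glom=st.integers(1, 60),
    n_scl=st.integers(0, 60),
    extra=st.integers(0, 10),
    ifta=st.floats(0, 90),
    bump=st.floats(0, 10),
    ratio=st.floats(1, 200),
    stretch=st.floats(1.0, 1.5),
)
def test_monotonicity_of_components_total_and_decision(
        n_glom, n_scl, extra, ifta, bump, ratio, stretch):
    """Increasing any raw injury measurement never decreases its score,
    the total, or the decision severity."""
    n_scl = min(n_scl, n_glom)
    sev = {"single": 0, "dual": 1, "discard": 2}

    def build(n_s, pct, r):
        return make_slide(n_glomeruli=n_glom, n_sclerosed=n_s, ifta_pct=pct,
                          arteries=[make_artery(r, "a1")])

    base = score_slide(build(n_scl, ifta, ratio))
    worse = score_slide(build(min(n_scl + extra, n_glom), min(ifta + bump, 100),
                              ratio * stretch))
    assert worse.score_gs >= base.score_gs
    assert worse.score_if >= base.score_if
    assert worse.score_art >= base.score_art
    assert worse.total >= base.total
    assert sev[worse.decision] >= sev[base.decision]


class TestThresholdConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = ThresholdConfig(gs_bands=(5, 25, 60), ifta_censor=3.0)
        p = tmp_path / "thr.yaml"
        cfg.to_yaml(p)
        assert ThresholdConfig.from_yaml(p) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            ThresholdConfig(arterio_bands=(80, 50, 120))
        with pytest.raises(ConfigurationError):
            ThresholdConfig(decision_single_max=6, decision_dual_max=6)
        with pytest.raises(ConfigurationError):
            ThresholdConfig.from_dict({"no_such_key": 1})

    def test_is_frozen(self, thresholds):
        with pytest.raises(dataclasses.FrozenInstanceError):
            thresholds.ifta_censor = 1.0
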