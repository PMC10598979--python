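"""Typing rules: signatures, precedence, phase assignment and evidence."""

import numpy as np
import pytest

from ventasync import (
    BreathCycle,
    PiecewiseFit,
    RuleConfig,
    classify_breath,
    evaluate_rule,
)
from ventasync.rules import ASYNCHRONY_TYPES


def make_fit(slopes, phase="inspiration", breakpoints=None,
             breakpoint_pressures=None, n_points=120):
    slopes = np.asarray(slopes, dtype=float)
    r = len(slopes)
    if breakpoints is None:
        breakpoints = np.linspace(0.1, 0.4, r - 1) if r > 1 else np.empty(0)
    if breakpoint_pressures is None:
        breakpoint_pressures = np.full(max(r - 1, 0), 12.0)
    return PiecewiseFit(
        r=r,
        breakpoints=np.asarray(breakpoints, dtype=float),
        breakpoint_pressures=np.asarray(breakpoint_pressures, dtype=float),
        breakpoint_indices=np.arange(1, r),
        slopes=slopes,
        intercepts=np.zeros(r),
        rsse=0.0,
        n_points=n_points,
        phase=phase,
    )


def make_breath(v_t=0.5, peep=5.0, end_volume=0.0, n=200):
    peak = n // 2
    vol = np.concatenate([
        np.linspace(0, v_t, peak + 1),
        np.linspace(v_t, end_volume, n - peak)[1:],
    ])
    pressure = np.full(n, peep)
    return BreathCycle(0, np.arange(n) / 100.0, pressure, np.zeros(n), vol, 0, n)


@pytest.fixture
def cfg():
    return RuleConfig()


@pytest.fixture
def breath():
    return make_breath()


class TestSignatures:
    def test_fa_signature_without_end_spike(self, breath, cfg):
        insp = make_fit([12, -6, 9, 10])
        ok, ev = evaluate_rule("fa", insp, None, breath, cfg)
        assert ok
        dc_ok, _ = evaluate_rule("dc", insp, None, breath, cfg)
        assert not dc_ok  # 10 < 2 * 9

    def test_dc_signature_with_end_spike(self, breath, cfg):
        insp = make_fit([12, -6, 4, 11])
        assert evaluate_rule("dc", insp, None, breath, cfg)[0]  # 11 > 2 * 4
        assert not evaluate_rule("fa", insp, None, breath, cfg)[0]

    def test_rt_signature(self, breath, cfg):
        insp = make_fit([10, 8, -5, 12])
        assert evaluate_rule("rt", insp, None, breath, cfg)[0]

    def test_pc_requires_early_notch(self, cfg):
        breath = make_breath(v_t=0.45)
        exp = make_fit([9, -5, 8, 8], phase="expiration",
                       breakpoints=[0.35, 0.25, 0.15])  # drop 0.1 < 0.225
        assert evaluate_rule("pc", None, exp, breath, cfg)[0]
        late = make_fit([9, -5, 8, 8], phase="expiration",
                        breakpoints=[0.10, 0.08, 0.05])  # drop 0.35 > 0.225
        assert not evaluate_rule("pc", None, late, breath, cfg)[0]

    def test_ie_requires_late_notch(self, breath, cfg):
        exp = make_fit([30, 90, -40, 30], phase="expiration",
                       breakpoints=[0.15, 0.11, 0.07])  # V_N0 - V_N2 = 0.39
        assert evaluate_rule("ie", None, exp, breath, cfg)[0]
        early = make_fit([30, 90, -40, 30], phase="expiration",
                         breakpoints=[0.45, 0.40, 0.35])
        assert not evaluate_rule("ie", None, early, breath, cfg)[0]

    def test_dt_breakpoint_pressure_conditions(self, cfg):
        breath = make_breath(peep=10.0)
        insp = make_fit([25, 18, 740, 80, 25],
                        breakpoint_pressures=[22.5, 19.4, 3.0, 15.0])
        assert evaluate_rule("dt", insp, None, breath, cfg)[0]
        # trigger-point pressure above PEEP kills the match
        bad = make_fit([25, 18, 740, 80, 25],
                       breakpoint_pressures=[22.5, 19.4, 11.0, 15.0])
        assert not evaluate_rule("dt", bad, None, breath, cfg)[0]

    def test_at_needs_volume_gap(self, cfg):
        leaky = make_breath(end_volume=0.06)
        insp = make_fit([30, 18], n_points=100)
        exp = make_fit([34, 21], phase="expiration", n_points=100)
        ok, ev = evaluate_rule("at", insp, exp, leaky,
                               RuleConfig(epsilon=0.04))
        assert ok and ev["volume_gap"] == pytest.approx(0.06)
        tight = make_breath(end_volume=0.0)
        assert not evaluate_rule("at", insp, exp, tight,
                                 RuleConfig(epsilon=0.04))[0]

    def test_normal_two_segment_breath_matches_nothing(self, breath, cfg):
        insp = make_fit([30, 18])
        exp = make_fit([34, 21], phase="expiration")
        for label in ASYNCHRONY_TYPES:
            assert not evaluate_rule(label, insp, exp, breath, cfg)[0]

    def test_unfittable_phase_is_false_not_error(self, breath, cfg):
        ok, ev = evaluate_rule("fa", None, make_fit([30, 18], "expiration"),
                               breath, cfg)
        assert not ok and ev.get("unfittable")


class TestClassifyBreath:
    def test_rt_only_match(self, breath, cfg):
        res = classify_breath(make_fit([10, 8, -5, 12]),
                              make_fit([34, 21], "expiration"), breath, cfg)
        assert res.primary_label == "rt"
        assert res.matched_rules == ("rt",)

    def test_dc_takes_precedence_and_fa_excluded(self, breath, cfg):
        res = classify_breath(make_fit([12, -6, 4, 11]),
                              make_fit([34, 21], "expiration"), breath, cfg)
        assert res.primary_label == "dc"
        assert "fa" not in res.matched_rules

    def test_both_halves_unfittable_is_none(self, breath, cfg):
        res = classify_breath(None, None, breath, cfg)
        assert res.primary_label == "none"
        assert res.matched_rules == ()

    def test_determinism(self, breath, cfg):
        insp, exp = make_fit([12, -6, 9, 10]), make_fit([34, 21], "expiration")
        a = classify_breath(insp, exp, breath, cfg)
        b = classify_breath(insp, exp, breath, cfg)
        assert a.primary_label == b.primary_label == "fa"
        assert a.matched_rules == b.matched_rules

    def test_label_phase_consistency_of_evidence(self, breath, cfg):
        insp = make_fit([12, -6, 9, 10])
        exp = make_fit([34, 21], "expiration")
        res = classify_breath(insp, exp, breath, cfg)
        for label in ("fa", "rt", "dc", "dt"):
            assert res.evidence[label]["phase"] == "inspiration"
        for label in ("pc", "ie"):
            assert res.evidence[label]["phase"] == "expiration"
        assert res.evidence["at"]["phase"] == "both"

    def test_primary_always_among_matches(self, breath, cfg):
        res = classify_breath(make_fit([12, -6, 9, 10]),
                              make_fit([34, 21], "expiration"), breath, cfg)
        assert res.primary_label in res.matched_rules

    def test_relaxed_fa_flag_accepts_three_segments(self, breath):
        cfg = RuleConfig(relaxed_fa=True)
        res = classify_breath(make_fit([12, -6, 9]),
                              make_fit([34, 21], "expiration"), breath, cfg)
        assert res.primary_label == "fa"
        strict = classify_breath(make_fit([12, -6, 9]),
                                 make_fit([34, 21], "expiration"), breath,
                                 RuleConfig())
        assert strict.primary_label == "none"


class TestRuleConfigValidation:
    def test_bad_epsilon_rejected(self):
        with pytest.raises(ValueError):
            RuleConfig(epsilon=0.0)

    def test_bad_slope_factor_rejected(self):
        with pytest.raises(ValueError):
            RuleConfig(dc_slope_factor=1.0)

    def test_precedence_must_cover_all_types(self):
        with pytest.raises(ValueError):
            RuleConfig(precedence=("fa", "rt"))
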