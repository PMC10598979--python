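"""Rule-based typing of patient-ventilator asynchrony from half-cycle fits.

Each asynchrony type leaves a characteristic distortion in the PV loop that
maps to a signature of the selected piecewise model: the segment count r,
the sign pattern of the local elastances k_s1..k_sr, and auxiliary breakpoint
conditions.  The seven types, their phase and their signatures:

==== ============ =====================================================================
code phase        signature
==== ============ =====================================================================
fa   inspiration  r=4; k1>0, k2<0, k3>0, k4>0 (early-inspiration pressure sag),
                  and NOT the dc end-inspiration spike condition
rt   inspiration  r=4; k1>0, k2>0, k3<0, k4>0 (delayed effort within the breath)
pc   expiration   r=4; k1>0, k2<0, k3>0, k4>0; V_N0 - V_N1 < V_T/2 (early notch)
dt   inspiration  r=5; k1>0, k1>k2, k3>k2, k4>k5; P_N3 < PEEP; P_N2>P_N3; P_N4>P_N3
dc   inspiration  r=4; k1>0, k2<0, k3>0, k4>0; k4 > 2*k3 (end-inspiration spike)
ie   expiration   r=4; k1>0, k2>0, k3<0, k4>0; V_N0 - V_N2 > V_T/2 (late notch)
at   whole loop   both halves r=2 with positive slopes; end-expiratory volume
                  exceeds the breath baseline by more than epsilon (circuit leak)
==== ============ =====================================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .regression import PiecewiseFit
from .waveform import BreathCycle

__all__ = [
    "ASYNCHRONY_TYPES",
    "LABELS",
    "RuleConfig",
    "BreathClassification",
    "evaluate_rule",
    "classify_breath",
]

ASYNCHRONY_TYPES = ("fa", "rt", "pc", "dt", "dc", "ie", "at")
LABELS = ASYNCHRONY_TYPES + ("none",)

#: which half-cycle each rule inspects
RULE_PHASE = {
    "fa": "inspiration",
    "rt": "inspiration",
    "dt": "inspiration",
    "dc": "inspiration",
    "pc": "expiration",
    "ie": "expiration",
    "at": "both",
}

DEFAULT_PRECEDENCE = ("dt", "dc", "fa", "rt", "pc", "ie", "at")


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds and knobs of the typing rules.

    Attributes
    ----------
    epsilon : float or None
        Absolute end-expiratory volume gap (L) for auto triggering; when
        ``None`` the relative gap ``epsilon_fraction * V_T`` is used.
    epsilon_fraction : float
        Relative gap threshold as a fraction of tidal volume.
    dc_slope_factor : float
        The end-inspiration spike factor: dc requires k4 > factor * k3.
    precedence : tuple
        Order in which matched rules resolve to the primary label.
    relaxed_fa : bool
        Accept a 3-segment early-sag variant (k1>0, k2<0, k3>0) as fa.
    """

    epsilon: float | None = None
    epsilon_fraction: float = 0.1
    dc_slope_factor: float = 2.0
    precedence: tuple = DEFAULT_PRECEDENCE
    relaxed_fa: bool = False

    def __post_init__(self):
        if self.epsilon is not None and not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not self.epsilon_fraction > 0:
            raise ValueError("epsilon_fraction must be positive")
        if not self.dc_slope_factor > 1:
            raise ValueError("dc_slope_factor must exceed 1")
        if set(self.precedence) != set(ASYNCHRONY_TYPES):
            raise ValueError("precedence must be a permutation of the 7 types")

    def epsilon_for(self, v_t: float) -> float:
        return self.epsilon if self.epsilon is not None else self.epsilon_fraction * v_t


@dataclass
class BreathClassification:
    """Per-breath label plus the evidence each rule evaluated."""

    breath_index: int
    primary_label: str
    matched_rules: tuple
    insp_fit: PiecewiseFit | None
    exp_fit: PiecewiseFit | None
    evidence: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "breath_index": self.breath_index,
            "primary_label": self.primary_label,
            "matched_rules": list(self.matched_rules),
            "insp_fit": self.insp_fit.to_dict() if self.insp_fit else None,
            "exp_fit": self.exp_fit.to_dict() if self.exp_fit else None,
            "evidence": self.evidence,
        }


def _slopes_ok(slopes: np.ndarray) -> bool:
    return not any(math.isnan(s) for s in slopes)


def _sign_pattern(fit: PiecewiseFit, signs: str) -> bool:
    """signs: one char per segment, '+' or '-'."""
    if fit.r != len(signs) or not _slopes_ok(fit.slopes):
        return False
    for s, want in zip(fit.slopes, signs):
        if want == "+" and not s > 0:
            return False
        if want == "-" and not s < 0:
            return False
    return True


def _dc_condition(fit: PiecewiseFit, factor: float) -> bool:
    return bool(fit.r == 4 and _slopes_ok(fit.slopes)
                and fit.slopes[3] > factor * fit.slopes[2])


def evaluate_rule(
    label: str,
    insp: PiecewiseFit | None,
    exp: PiecewiseFit | None,
    breath: BreathCycle,
    cfg: RuleConfig,
) -> tuple[bool, dict]:
    """Evaluate one typing predicate; returns (matched, evidence).

    A rule whose required half-cycle fit is missing (unfittable) is false,
    never an error.
    """
    ev: dict = {"rule": label, "phase": RULE_PHASE[label]}

    if label == "fa":
        if insp is None:
            return False, {**ev, "unfittable": True}
        ev["slopes"] = list(insp.slopes)
        base = _sign_pattern(insp, "+-++") and not _dc_condition(insp, cfg.dc_slope_factor)
        if not base and cfg.relaxed_fa:
            base = _sign_pattern(insp, "+-+")
            ev["relaxed_3seg"] = base
        return base, ev

    if label == "rt":
        if insp is None:
            return False, {**ev, "unfittable": True}
        ev["slopes"] = list(insp.slopes)
        return _sign_pattern(insp, "++-+"), ev

    if label == "dc":
        if insp is None:
            return False, {**ev, "unfittable": True}
        ev["slopes"] = list(insp.slopes)
        ev["dc_slope_factor"] = cfg.dc_slope_factor
        return bool(_sign_pattern(insp, "+-++")
                    and _dc_condition(insp, cfg.dc_slope_factor)), ev

    if label == "dt":
        if insp is None:
            return False, {**ev, "unfittable": True}
        ev["slopes"] = list(insp.slopes)
        if insp.r != 5 or not _slopes_ok(insp.slopes):
            return False, ev
        k = insp.slopes
        pn = insp.breakpoint_pressures  # P_N1..P_N4
        ev["breakpoint_pressures"] = list(pn)
        ev["peep"] = breath.peep
        ok = (
            k[0] > 0
            and k[0] > k[1]
            and k[2] > k[1]
            and k[3] > k[4]
            and pn[2] < breath.peep       # P_N3 < PEEP
            and pn[1] > pn[2]             # P_N2 > P_N3
            and pn[3] > pn[2]             # P_N4 > P_N3
        )
        return bool(ok), ev

    if label == "pc":
        if exp is None:
            return False, {**ev, "unfittable": True}
        ev["slopes"] = list(exp.slopes)
        if not _sign_pattern(exp, "+-++"):
            return False, ev
        # N_0 is the first expiratory point (volume = V_T); V_N0 - V_N1 is the
        # volume already exhaled when the notch starts.
        drop = breath.v_t - float(exp.breakpoints[0])
        ev.update({"v_drop_to_notch": drop, "half_vt": breath.v_t / 2})
        return bool(drop < breath.v_t / 2), ev

    if label == "ie":
        if exp is None:
            return False, {**ev, "unfittable": True}
        ev["slopes"] = list(exp.slopes)
        if not _sign_pattern(exp, "++-+"):
            return False, ev
        v_n0 = breath.v_t
        drop = v_n0 - float(exp.breakpoints[1])
        ev.update({"v_drop_to_notch": drop, "half_vt": breath.v_t / 2})
        return bool(drop > breath.v_t / 2), ev

    if label == "at":
        if insp is None or exp is None:
            return False, {**ev, "unfittable": True}
        eps = cfg.epsilon_for(breath.v_t)
        gap = float(breath.volume[-1] - breath.volume[0])
        ev.update({"volume_gap": gap, "epsilon": eps,
                   "insp_slopes": list(insp.slopes), "exp_slopes": list(exp.slopes)})
        ok = (
            insp.r == 2 and exp.r == 2
            and _sign_pattern(insp, "++") and _sign_pattern(exp, "++")
            and gap > eps
        )
        return bool(ok), ev

    raise ValueError(f"unknown rule {label!r}")


def classify_breath(
    insp: PiecewiseFit | None,
    exp: PiecewiseFit | None,
    breath: BreathCycle,
    cfg: RuleConfig | None = None,
) -> BreathClassification:
    """Evaluate all seven typing rules and resolve a primary label.

    The primary label is the first match in the configured precedence order;
    ``none`` if no rule fires or both half-cycles were unfittable.
    """
    cfg = cfg or RuleConfig()
    matched: list[str] = []
    evidence: dict = {}
    if insp is None and exp is None:
        return BreathClassification(
            breath.breath_index, "none", (), None, None, {"unfittable": True}
        )
    for label in cfg.precedence:
        ok, ev = evaluate_rule(label, insp, exp, breath, cfg)
        evidence[label] = ev
        if ok:
            matched.append(label)
    primary = matched[0] if matched else "none"
    return BreathClassification(
        breath.breath_index, primary, tuple(matched), insp, exp, evidence
    )
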