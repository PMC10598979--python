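"""Synthetic ventilated-breath generator with labelled asynchrony archetypes.

The generator produces airway pressure / flow waveforms whose PV loops are
exact piecewise-linear curves (a quasi-static loop model): the inspiratory
limb follows the single-compartment relation

    P = E(V) * V + R * Q + PEEP - P_mus,

with a volume-controlled square flow profile and an optional two-regime
elastance (a lower inflection "knee"), while the expiratory limb is drawn as
a relaxation polyline from the end-inspiratory pressure down to PEEP over an
exponentially decaying volume.  Patient-effort distortions (P_mus bumps and
expiratory notches) are piecewise linear in the volume coordinate, so every
archetype's segment signature is exact at zero noise and ground-truth labels
are meaningful.  Additive i.i.d. Gaussian noise models the measurement chain.

Archetype catalogue (`ARCHETYPE_LABELS`): normal breaths plus the seven
asynchrony types fa, rt, pc, dt, dc, ie, at.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .waveform import BreathCycle, WaveformRecord

__all__ = [
    "SimConfig",
    "EffortEvent",
    "ConfigError",
    "ARCHETYPE_LABELS",
    "DEFAULT_MIX",
    "DEMO_MIX",
    "archetype_event",
    "archetype_config",
    "simulate_breath",
    "simulate_sequence",
]

ARCHETYPE_LABELS = ("fa", "rt", "pc", "dt", "dc", "ie", "at")

#: default per-type incidence for cohort simulations (~35% asynchronous,
#: within the clinically reported range for unselected ICU cohorts)
DEFAULT_MIX = {label: 0.05 for label in ARCHETYPE_LABELS}

#: a flow-asynchrony / reverse-triggering dominated mix used in examples
DEMO_MIX = {"rt": 0.36, "fa": 0.15}


class ConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Ventilator and respiratory-mechanics settings for one breath stream.

    Attributes
    ----------
    mode : str
        "VC" (volume-controlled, square flow) or "PC" (pressure-controlled).
    elastance : float
        Respiratory-system elastance above the knee, cmH2O/L.
    elastance_low : float or None
        Elastance below the knee volume; ``None`` disables the knee
        (single-regime linear compliance).
    knee_fraction : float
        Knee volume as a fraction of tidal volume.
    resistance : float
        Airway resistance, cmH2O.s/L.
    peep : float
        Set positive end-expiratory pressure, cmH2O.
    rate : float
        Respiratory rate, breaths/min.
    ie_ratio : float
        Expiratory-to-inspiratory time ratio (2.0 means I:E = 1:2).
    tidal_volume : float
        Target tidal volume, L (VC mode).
    pressure_target : float
        Inspiratory pressure above PEEP, cmH2O (PC mode).
    exp_knee : bool
        Draw the expiratory relaxation limb with a two-slope knee.
    noise_sd_pressure, noise_sd_flow : float
        Gaussian measurement noise, cmH2O and L/s.
    sample_rate : float
        Hz.
    seed : int
        Seed for the breath-level RNG when none is supplied.
    """

    mode: str = "VC"
    elastance: float = 18.0
    elastance_low: float | None = 30.0
    knee_fraction: float = 0.35
    resistance: float = 10.0
    peep: float = 5.0
    rate: float = 15.0
    ie_ratio: float = 2.0
    tidal_volume: float = 0.5
    pressure_target: float = 12.0
    exp_knee: bool = True
    noise_sd_pressure: float = 0.2
    noise_sd_flow: float = 0.01
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("VC", "PC"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for name in ("elastance", "resistance", "rate", "tidal_volume",
                     "sample_rate", "ie_ratio"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.noise_sd_pressure < 0 or self.noise_sd_flow < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.peep < 0:
            raise ConfigError("peep must be >= 0")

    @property
    def cycle_duration(self) -> float:
        return 60.0 / self.rate

    @property
    def insp_duration(self) -> float:
        return self.cycle_duration / (1.0 + self.ie_ratio)

    @property
    def exp_duration(self) -> float:
        return self.cycle_duration - self.insp_duration

    @property
    def insp_flow(self) -> float:
        return self.tidal_volume / self.insp_duration


@dataclass(frozen=True)
class EffortEvent:
    """One patient-effort (or leak) distortion applied to a breath.

    ``onset`` is the distortion onset as a fraction of the relevant limb's
    volume excursion; ``amplitude`` scales the pressure distortion in cmH2O;
    ``leak_rate`` (L/s, auto-triggering only) sets the circuit leak;
    ``extra_trigger`` marks a stacked second ventilator cycle (dt only).
    """

    target_label: str
    onset: float = 0.1
    duration: float = 0.5
    amplitude: float = 4.0
    leak_rate: float = 0.0
    extra_trigger: bool = False

    def __post_init__(self):
        if self.target_label not in ARCHETYPE_LABELS:
            raise ConfigError(f"unknown archetype {self.target_label!r}")
        if not 0 <= self.onset < 1:
            raise ConfigError("onset must lie in [0, 1)")
        if self.amplitude < 0 or self.leak_rate < 0:
            raise ConfigError("amplitude and leak_rate must be >= 0")
        if self.target_label == "dt" and not self.extra_trigger:
            raise ConfigError("dt requires extra_trigger=True")


def archetype_event(label: str, amplitude: float | None = None) -> EffortEvent | None:
    """Canonical effort event for one archetype (None = normal breath)."""
    if label in ("none", "normal", None):
        return None
    defaults = {
        "fa": EffortEvent("fa", onset=0.10, duration=0.35, amplitude=4.0),
        "rt": EffortEvent("rt", onset=0.60, duration=0.40, amplitude=4.0),
        "dc": EffortEvent("dc", onset=0.15, duration=0.85, amplitude=4.0),
        "pc": EffortEvent("pc", onset=0.25, duration=0.20, amplitude=4.0),
        "ie": EffortEvent("ie", onset=0.70, duration=0.16, amplitude=4.0),
        "at": EffortEvent("at", amplitude=0.0, leak_rate=0.04),
        "dt": EffortEvent("dt", onset=0.60, amplitude=4.0, extra_trigger=True),
    }
    if label not in defaults:
        raise ConfigError(f"unknown archetype {label!r}")
    ev = defaults[label]
    if amplitude is not None:
        ev = replace(ev, amplitude=amplitude)
    return ev


def archetype_config(label: str, base: SimConfig) -> SimConfig:
    """Mechanics preset for one archetype, derived from a base configuration.

    Inspiratory-sag types (fa, dc) and the expiratory-notch types (pc, ie)
    plus the stacked-breath type (dt) use a single-regime elastance so the
    distortion, not the knee, owns the extra segments; ie additionally uses a
    straight expiratory relaxation line for the same reason.
    """
    if label in ("none", "normal", None, "rt", "at"):
        return base
    if label in ("fa", "dc", "dt", "pc"):
        return replace(base, elastance_low=None, elastance=25.0)
    if label == "ie":
        return replace(base, elastance_low=None, elastance=25.0, exp_knee=False)
    raise ConfigError(f"unknown archetype {label!r}")


# ---------------------------------------------------------------------------
# clean-limb construction
# ---------------------------------------------------------------------------

def _recoil(v: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Elastic recoil pressure E(V)*V, piecewise linear with optional knee."""
    if cfg.elastance_low is None:
        return cfg.elastance * v
    vk = cfg.knee_fraction * cfg.tidal_volume
    return np.where(
        v <= vk,
        cfg.elastance_low * v,
        cfg.elastance_low * vk + cfg.elastance * (v - vk),
    )


def _p_top(cfg: SimConfig) -> float:
    """End-inspiratory pressure of an undistorted breath."""
    vt = np.array([cfg.tidal_volume])
    if cfg.mode == "PC":
        return cfg.peep + cfg.pressure_target
    return float(cfg.peep + cfg.resistance * cfg.insp_flow + _recoil(vt, cfg)[0])


def _triangle(x: np.ndarray, x0: float, xp: float, x1: float, amp: float) -> np.ndarray:
    """Piecewise-linear bump: 0 at x0, amp at xp, 0 at x1."""
    up = np.clip((x - x0) / max(xp - x0, 1e-9), 0.0, 1.0)
    down = np.clip((x1 - x) / max(x1 - xp, 1e-9), 0.0, 1.0)
    return amp * np.minimum(up, down)


def _trapezoid(x: np.ndarray, x0: float, x1: float, x2: float, x3: float,
               amp: float) -> np.ndarray:
    """Piecewise-linear plateau bump: rises x0->x1, flat x1->x2, falls x2->x3."""
    up = np.clip((x - x0) / max(x1 - x0, 1e-9), 0.0, 1.0)
    down = np.clip((x3 - x) / max(x3 - x2, 1e-9), 0.0, 1.0)
    return amp * np.minimum(up, down)


def _insp_limb(cfg: SimConfig, bump: np.ndarray | None = None):
    """Volume, pressure, flow over samples 0..n_i (peak inclusive)."""
    n_i = int(round(cfg.insp_duration * cfg.sample_rate))
    frac = np.arange(n_i + 1) / n_i
    v = cfg.tidal_volume * frac
    if cfg.mode == "PC":
        # steep initial pressurisation then a gentle positive slope
        dp = cfg.pressure_target
        knots_v = np.array([0.0, 0.15 * cfg.tidal_volume, cfg.tidal_volume])
        knots_p = np.array([cfg.peep + 0.1 * dp, cfg.peep + 0.85 * dp, cfg.peep + dp])
        p = np.interp(v, knots_v, knots_p)
        q = np.full(n_i + 1, cfg.insp_flow)
    else:
        p = cfg.peep + cfg.resistance * cfg.insp_flow + _recoil(v, cfg)
        q = np.full(n_i + 1, cfg.insp_flow)
    if bump is not None:
        p = p - bump
    return v, p, q


def _exp_volume(cfg: SimConfig, v_start: float, v_end: float, duration: float):
    """Exponential volume decay reaching v_end exactly at `duration`.

    The time constant is duration/3 so terminal flow stays clearly negative
    (about -3% of the excursion per time constant), keeping breath onset
    detection unambiguous under flow noise.
    """
    n_e = int(round(duration * cfg.sample_rate))
    t = np.arange(1, n_e + 1) / cfg.sample_rate
    t_end = n_e / cfg.sample_rate  # actual sampled duration after rounding
    tau = t_end / 3.0
    norm = 1.0 - math.exp(-t_end / tau)
    decay = (np.exp(-t / tau) - math.exp(-t_end / tau)) / norm
    v = v_end + (v_start - v_end) * decay
    q = -(v_start - v_end) / tau * np.exp(-t / tau) / norm
    return v, q


def _relax_polyline(cfg: SimConfig, p_top: float, v_start: float, v_end: float):
    """Knots (descending V) of the passive expiratory relaxation limb."""
    if cfg.exp_knee:
        vk = v_end + cfg.knee_fraction * (v_start - v_end)
        pk = cfg.peep + 0.25 * (p_top - cfg.peep)
        return [(v_start, p_top), (vk, pk), (v_end, cfg.peep)]
    return [(v_start, p_top), (v_end, cfg.peep)]


def _interp_polyline(v: np.ndarray, knots: list[tuple[float, float]]) -> np.ndarray:
    kv = np.array([k[0] for k in knots])[::-1]  # ascending V for np.interp
    kp = np.array([k[1] for k in knots])[::-1]
    return np.interp(v, kv, kp)


def _exp_limb(cfg: SimConfig, p_top: float, v_end: float = 0.0,
              knots: list[tuple[float, float]] | None = None):
    v, q = _exp_volume(cfg, cfg.tidal_volume, v_end, cfg.exp_duration)
    if knots is None:
        knots = _relax_polyline(cfg, p_top, cfg.tidal_volume, v_end)
    p = _interp_polyline(v, knots)
    return v, p, q


# ---------------------------------------------------------------------------
# archetype builders (clean waveforms)
# ---------------------------------------------------------------------------

def _build_simple(cfg: SimConfig, event: EffortEvent | None):
    """Normal breath, inspiratory bump types (fa, rt, dc) and leak (at)."""
    label = event.target_label if event else "none"
    n_i = int(round(cfg.insp_duration * cfg.sample_rate))
    frac = np.arange(n_i + 1) / n_i

    bump = None
    if label == "fa":
        x0 = event.onset
        bump = _triangle(frac, x0, x0 + 0.57 * event.duration, x0 + event.duration,
                         event.amplitude)
    elif label == "rt":
        x0 = event.onset
        bump = _triangle(frac, x0, x0 + 0.5 * event.duration,
                         min(x0 + event.duration, 1.0), event.amplitude)
    elif label == "dc":
        # plateau ending exactly at end-inspiration: air-trapping spike
        x0 = event.onset
        x3 = min(x0 + event.duration, 1.0)
        bump = _trapezoid(frac, x0, x0 + 0.29 * (x3 - x0), x3 - 0.18 * (x3 - x0),
                          x3, event.amplitude)

    vi, pi, qi = _insp_limb(cfg, bump)
    v_end = event.leak_rate * cfg.exp_duration if (event and label == "at") else 0.0
    ve, pe, qe = _exp_limb(cfg, float(pi[-1]), v_end=v_end)
    v = np.concatenate([vi, ve])
    p = np.concatenate([pi, pe])
    q = np.concatenate([qi, qe])
    return v, p, q


def _build_exp_notch(cfg: SimConfig, event: EffortEvent):
    """Expiratory notch types: premature cycling (early) / ineffective effort (late).

    The notch is a depression below the relaxation line: a merged steep
    descent, a recovery traversed with volume still falling (hence a
    negative PV slope), then the remaining relaxation.
    """
    label = event.target_label
    vi, pi, qi = _insp_limb(cfg, None)
    p_top = float(pi[-1])
    vt = cfg.tidal_volume
    relax = _relax_polyline(cfg, p_top, vt, 0.0)
    depth = 1.1 * event.amplitude

    if label == "pc":
        # notch starts after `onset` of the excursion has been exhaled
        v1 = vt * (1.0 - event.onset)          # notch bottom
        v2 = vt * (1.0 - event.onset - event.duration)  # recovery rejoins line
        p1 = _interp_polyline(np.array([v1]), relax)[0] - depth
        p2 = _interp_polyline(np.array([v2]), relax)[0]
        knots = [(vt, p_top), (v1, p1), (v2, p2)]
        knots += [k for k in relax[1:] if k[0] < v2]
        if knots[-1][0] != 0.0:
            knots.append((0.0, cfg.peep))
    elif label == "ie":
        v1 = vt * (1.0 - event.onset)          # descent start, on the line
        v2 = v1 - 0.5 * event.duration * vt    # notch bottom
        v3 = v2 - 0.5 * event.duration * vt    # recovery rejoins line
        p1 = _interp_polyline(np.array([v1]), relax)[0]
        p2 = _interp_polyline(np.array([v2]), relax)[0] - depth
        p3 = _interp_polyline(np.array([v3]), relax)[0]
        knots = [(vt, p_top), (v1, p1), (v2, p2), (v3, p3)]
        knots += [k for k in relax[1:] if k[0] < v3]
        if knots[-1][0] != 0.0:
            knots.append((0.0, cfg.peep))
    else:  # pragma: no cover
        raise ConfigError(label)

    ve, pe, qe = _exp_limb(cfg, p_top, v_end=0.0, knots=knots)
    return (np.concatenate([vi, ve]), np.concatenate([pi, pe]),
            np.concatenate([qi, qe]))


def _build_double_trigger(cfg: SimConfig, event: EffortEvent):
    """Two stacked ventilator cycles: incomplete expiration, sub-PEEP trigger
    dip, then a second insufflation; the inspiratory half-cycle (up to the
    global volume peak) carries five segments."""
    fs = cfg.sample_rate
    dt = 1.0 / fs
    vt = cfg.tidal_volume
    q0 = cfg.insp_flow
    e = cfg.elastance if cfg.elastance_low is None else cfg.elastance_low

    # S1: first insufflation (square flow)
    n1 = int(round(cfg.insp_duration * fs))
    v1 = vt * np.arange(n1 + 1) / n1
    p1 = cfg.peep + cfg.resistance * q0 + e * v1
    q1 = np.full(n1 + 1, q0)
    p_top1 = float(p1[-1])

    # S2: incomplete expiration down to ~62% of VT along a shallow line
    v_b = 0.62 * vt
    t_pe = 0.8
    v2, q2 = _exp_volume(cfg, vt, v_b, t_pe)
    s2 = 0.72 * e  # partial-relaxation slope, below the inspiratory slope
    p2 = p_top1 - s2 * (vt - v2)
    p_b = float(p2[-1])

    # S3: patient trigger effort: short sharp dip below PEEP
    dip = max(0.5, 0.5 * event.amplitude)
    v_c = v_b - 0.04 * vt
    p_c = cfg.peep - dip
    n3 = max(int(round(0.10 * fs)), 5)
    fr3 = np.arange(1, n3 + 1) / n3
    v3 = v_b + (v_c - v_b) * fr3
    p3 = p_b + (p_c - p_b) * fr3
    q3 = np.full(n3, (v_c - v_b) / (n3 * dt))

    # S4+S5: second insufflation, fast repressurisation then normal slope
    v_d = v_c + 0.22 * vt
    v_peak = v_c + 0.92 * vt
    p_d = p_c + (cfg.resistance * q0 + e * (v_d - v_c)) + 0.55 * event.amplitude
    p_peak = p_d + e * (v_peak - v_d)
    n45 = int(round(0.9 * cfg.insp_duration * fs))
    fr45 = np.arange(1, n45 + 1) / n45
    v45 = v_c + (v_peak - v_c) * fr45
    p45 = np.interp(v45, [v_c, v_d, v_peak], [p_c, p_d, p_peak])
    q45 = np.full(n45, (v_peak - v_c) / (n45 * dt))

    # final full expiration from the stacked peak
    ve, qe = _exp_volume(cfg, v_peak, 0.0, cfg.exp_duration)
    knots = _relax_polyline(cfg, float(p_peak), v_peak, 0.0)
    pe = _interp_polyline(ve, knots)

    v = np.concatenate([v1, v2, v3, v45, ve])
    p = np.concatenate([p1, p2, p3, p45, pe])
    q = np.concatenate([q1, q2, q3, q45, qe])
    return v, p, q


def _consistent_flow(v: np.ndarray, q0: float, dt: float) -> np.ndarray:
    """Flow trace whose trapezoidal integral reproduces ``v`` exactly.

    Solves q[i+1] = 2*(v[i+1]-v[i])/dt - q[i] in closed form; the departure
    from the analytic derivative is an alternating ripple bounded by the
    initial discretisation mismatch (~1e-4 L/s here), far below both the
    onset-detection threshold and the flow noise floor.
    """
    dv = np.diff(v)
    signs = np.where(np.arange(len(dv)) % 2 == 0, 1.0, -1.0)
    partial = np.cumsum(signs * dv)
    q = np.empty(len(v))
    q[0] = q0
    k = np.arange(1, len(v))
    q[1:] = ((-1.0) ** k) * q0 + (2.0 / dt) * ((-1.0) ** (k - 1)) * partial
    return q


def _build(label: str, cfg: SimConfig, event: EffortEvent | None):
    cfg = archetype_config(label, cfg)
    if cfg.mode == "PC" and label not in ("none", "at"):
        raise ConfigError(
            f"archetype {label!r} is only generated under the VC preset"
        )
    if label in ("none", "fa", "rt", "dc", "at"):
        v, p, q = _build_simple(cfg, event)
    elif label in ("pc", "ie"):
        v, p, q = _build_exp_notch(cfg, event)
    elif label == "dt":
        v, p, q = _build_double_trigger(cfg, event)
    else:
        raise ConfigError(f"unknown archetype {label!r}")
    # measured flow for the 'at' leak: the constructed volume already includes
    # the un-returned leak volume, so consistency with it is what we want
    q = _consistent_flow(v, float(q[0]), 1.0 / cfg.sample_rate)
    return v, p, q


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_breath(
    cfg: SimConfig,
    event: EffortEvent | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BreathCycle, str]:
    """Generate one breath; returns the cycle and its ground-truth label."""
    label = event.target_label if event is not None else "none"
    v, p, q = _build(label, cfg, event)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd_pressure > 0:
        p = p + rng.normal(0.0, cfg.noise_sd_pressure, len(p))
    if cfg.noise_sd_flow > 0:
        q = q + rng.normal(0.0, cfg.noise_sd_flow, len(q))
    t = np.arange(len(v)) / cfg.sample_rate
    breath = BreathCycle(
        breath_index=0, time=t, pressure=p, flow=q, volume=v,
        start_sample=0, end_sample=len(v),
    )
    return breath, label


def allocate_labels(mix: dict, n_breaths: int,
                    rng: np.random.Generator) -> list[str]:
    """Deterministic largest-remainder allocation of labels, then shuffled."""
    if n_breaths < 1:
        raise ConfigError("n_breaths must be >= 1")
    fracs = {k: float(v) for k, v in mix.items()}
    for k, v in fracs.items():
        if k not in ARCHETYPE_LABELS:
            raise ConfigError(f"unknown label {k!r} in mix")
        if v < 0:
            raise ConfigError("mix fractions must be >= 0")
    total = sum(fracs.values())
    if total > 1.0 + 1e-9:
        raise ConfigError("mix fractions must sum to <= 1")
    counts = {k: int(math.floor(v * n_breaths)) for k, v in fracs.items()}
    remainders = sorted(
        fracs, key=lambda k: (fracs[k] * n_breaths - counts[k], k), reverse=True
    )
    short = round(sum(fracs.values()) * n_breaths) - sum(counts.values())
    for k in remainders[: max(short, 0)]:
        counts[k] += 1
    labels = [k for k, c in counts.items() for _ in range(c)]
    labels += ["none"] * (n_breaths - len(labels))
    order = rng.permutation(len(labels))
    return [labels[i] for i in order]


def simulate_sequence(
    cfg: SimConfig,
    mix: dict | None,
    n_breaths: int,
    seed: int | None = None,
) -> tuple[WaveformRecord, list[str]]:
    """Concatenate labelled breaths into one uniformly sampled record.

    Label counts match ``mix`` fractions within +/-1 (largest-remainder
    allocation), shuffled by the seed; identical (cfg, mix, n, seed) inputs
    reproduce the record and labels bit-for-bit.
    """
    mix = dict(mix or {})
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labels = allocate_labels(mix, n_breaths, rng)

    vs, ps, qs = [], [], []
    for label in labels:
        v, p, q = _build(label, cfg, archetype_event(label))
        vs.append(v)
        ps.append(p)
        qs.append(q)
    p = np.concatenate(ps)
    q = np.concatenate(qs)
    if cfg.noise_sd_pressure > 0:
        p = p + rng.normal(0.0, cfg.noise_sd_pressure, len(p))
    if cfg.noise_sd_flow > 0:
        q = q + rng.normal(0.0, cfg.noise_sd_flow, len(q))
    t = np.arange(len(p)) / cfg.sample_rate
    record = WaveformRecord(time=t, pressure=p, flow=q, sample_rate=cfg.sample_rate)
    return record, labels
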