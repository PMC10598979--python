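"""Ventilator waveform I/O, volume integration, breath segmentation and PV half-cycles.

Units are fixed throughout the package: time in seconds, airway pressure in
cmH2O, flow in L/s (positive = inspiratory), volume in L.  Converters, if
needed, belong at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WaveformRecord",
    "BreathCycle",
    "HalfCycle",
    "DataError",
    "FormatError",
    "read_waveform",
    "write_waveform",
    "integrate_volume",
    "segment_breaths",
    "split_half_cycles",
]

DEFAULT_COLUMNS = {"time": "time_s", "pressure": "paw_cmH2O", "flow": "flow_Lps"}


class DataError(ValueError):
    """Raised for physically or structurally invalid waveform data."""


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass(frozen=True)
class WaveformRecord:
    """A uniformly sampled airway pressure / flow stream.

    Attributes
    ----------
    time : ndarray
        Sample times, s. Strictly increasing on a uniform grid.
    pressure : ndarray
        Airway pressure, cmH2O.
    flow : ndarray
        Flow at the airway opening, L/s; positive during inspiration.
    sample_rate : float
        Sampling frequency, Hz; must match the median grid spacing.
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    sample_rate: float

    def __post_init__(self):
        t, p, q = (np.asarray(a, dtype=float) for a in (self.time, self.pressure, self.flow))
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pressure", p)
        object.__setattr__(self, "flow", q)
        n = len(t)
        if not (len(p) == len(q) == n) or n < 2:
            raise DataError("time, pressure and flow must share a length >= 2")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError("time must be strictly increasing")
        med = float(np.median(dt))
        if np.any(np.abs(dt - med) > 1e-6 * max(med, 1.0)):
            raise DataError("sampling grid is not uniform")
        if abs(self.sample_rate * med - 1.0) > 1e-3:
            raise DataError(
                f"sample_rate {self.sample_rate} Hz inconsistent with spacing {med} s"
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class BreathCycle:
    """One detected breath with volume re-baselined to zero at its first sample."""

    breath_index: int
    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray          # L, volume[0] == 0
    start_sample: int           # index into the parent record
    end_sample: int             # exclusive
    v_t: float = field(init=False)          # tidal volume, L
    peep: float = field(init=False)         # cmH2O, pressure at breath start
    peak_volume_index: int = field(init=False)

    def __post_init__(self):
        v = np.asarray(self.volume, dtype=float)
        v = v - v[0]
        self.volume = v
        # first sample attaining the maximum (tie-break: earliest)
        self.peak_volume_index = int(np.argmax(v))
        self.v_t = float(v[self.peak_volume_index])
        self.peep = float(self.pressure[0])

    @property
    def fittable(self) -> bool:
        """Both half-cycles must exist: the peak cannot sit at either end."""
        return 0 < self.peak_volume_index < len(self.volume) - 1 and self.v_t > 0

    def __len__(self) -> int:
        return len(self.volume)


@dataclass
class HalfCycle:
    """Ordered (V, P) trace of one limb of a PV loop, in traversal order."""

    phase: str                  # "inspiration" | "expiration"
    volume: np.ndarray
    pressure: np.ndarray

    def __post_init__(self):
        if self.phase not in ("inspiration", "expiration"):
            raise ValueError(f"unknown phase {self.phase!r}")
        self.volume = np.asarray(self.volume, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if len(self.volume) != len(self.pressure):
            raise DataError("volume/pressure length mismatch in half-cycle")

    @property
    def n_points(self) -> int:
        return len(self.volume)

    def fittable(self, r_max: int = 5, min_segment_points: int = 2) -> bool:
        return self.n_points >= max(2 * (r_max + 1), 2 * min_segment_points)


def integrate_volume(flow: np.ndarray, dt: float) -> np.ndarray:
    """Cumulative trapezoidal integral of flow (L/s) over a uniform grid.

    Returns volume in L with volume[0] == 0.
    """
    flow = np.asarray(flow, dtype=float)
    if flow.size == 0:
        raise DataError("cannot integrate an empty flow trace")
    if dt <= 0:
        raise DataError("dt must be positive")
    out = np.empty_like(flow)
    out[0] = 0.0
    if flow.size > 1:
        out[1:] = np.cumsum((flow[1:] + flow[:-1]) * (0.5 * dt))
    return out


def read_waveform(path, *, delimiter: str = ",", columns: dict | None = None) -> WaveformRecord:
    """Read a delimited text waveform file into a validated :class:`WaveformRecord`.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row.
    delimiter : str
        Field separator.
    columns : dict, optional
        Mapping with keys ``time``, ``pressure``, ``flow`` (and optionally
        ``volume``) giving the column names; defaults to
        ``time_s, paw_cmH2O, flow_Lps``.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    for key in ("time", "pressure", "flow"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing column {cols[key]!r} for {key} in {path}")
    rec_kwargs = dict(
        time=df[cols["time"]].to_numpy(float),
        pressure=df[cols["pressure"]].to_numpy(float),
        flow=df[cols["flow"]].to_numpy(float),
    )
    t = rec_kwargs["time"]
    if len(t) >= 2:
        spacing = np.median(np.diff(t))
        if spacing <= 0:
            raise DataError("time column is not strictly increasing")
        rate = 1.0 / float(spacing)
    else:
        raise DataError("waveform needs at least two samples")
    return WaveformRecord(sample_rate=rate, **rec_kwargs)


def write_waveform(path, record: WaveformRecord, *, delimiter: str = ",",
                   columns: dict | None = None) -> None:
    """Write a record as CSV in the dialect :func:`read_waveform` consumes.

    Values round-trip exactly (written with repr-precision floats).
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.DataFrame({
        cols["time"]: record.time,
        cols["pressure"]: record.pressure,
        cols["flow"]: record.flow,
    })
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def segment_breaths(
    record: WaveformRecord,
    *,
    min_insp_duration: float = 0.05,
    flow_threshold: float = 0.01,
    volume: np.ndarray | None = None,
    volume_gate_fraction: float = 0.5,
) -> list[BreathCycle]:
    """Split a record into breaths at sustained inspiratory flow onsets.

    A breath onset is a crossing of flow from <= ``flow_threshold`` to
    > ``flow_threshold`` sustained for at least ``min_insp_duration``.  A
    candidate onset is rejected while the running volume still exceeds
    ``volume_gate_fraction`` of the peak volume since the previous onset, so
    that a second ventilator cycle stacked on an incomplete expiration (a
    double-trigger) stays merged into a single breath.

    Parameters
    ----------
    volume : ndarray, optional
        Pre-computed volume trace (L) overriding flow integration.
    """
    q = record.flow
    n = len(q)
    sustain = max(1, int(round(min_insp_duration * record.sample_rate)))
    if volume is None:
        vol = integrate_volume(q, record.dt)
    else:
        vol = np.asarray(volume, dtype=float)
        if len(vol) != n:
            raise DataError("volume override length mismatch")

    above = q > flow_threshold
    # sustained[i]: samples i .. i+sustain-1 all above threshold
    if sustain > 1:
        kernel = np.ones(sustain, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == sustain
        sustained = np.zeros(n, dtype=bool)
        sustained[: len(runs)] = runs
    else:
        sustained = above
    crossing = np.zeros(n, dtype=bool)
    crossing[0] = sustained[0]
    crossing[1:] = sustained[1:] & ~above[:-1]

    onsets: list[int] = []
    last_onset = None
    peak_since = 0.0
    candidate_idx = np.flatnonzero(crossing)
    for i in candidate_idx:
        if last_onset is None:
            onsets.append(int(i))
            last_onset = int(i)
            continue
        seg_vol = vol[last_onset: i + 1] - vol[last_onset]
        peak_since = float(seg_vol.max(initial=0.0))
        if peak_since > 0 and (seg_vol[-1] > volume_gate_fraction * peak_since):
            continue  # expiration incomplete: merge (double-trigger semantics)
        onsets.append(int(i))
        last_onset = int(i)

    breaths: list[BreathCycle] = []
    bounds = onsets + [n]
    for k in range(len(onsets)):
        s, e = bounds[k], bounds[k + 1]
        if e - s < 2:
            continue
        breaths.append(
            BreathCycle(
                breath_index=len(breaths),
                time=record.time[s:e],
                pressure=record.pressure[s:e],
                flow=record.flow[s:e],
                volume=vol[s:e] - vol[s],
                start_sample=s,
                end_sample=e,
            )
        )
    return breaths


def split_half_cycles(breath: BreathCycle) -> tuple[HalfCycle, HalfCycle]:
    """Split a breath's PV loop at the turning point of maximum volume.

    Inspiration covers samples [0, peak], expiration [peak, end]; the peak
    sample is shared so both limbs meet at tidal volume.
    """
    k = breath.peak_volume_index
    insp = HalfCycle("inspiration", breath.volume[: k + 1], breath.pressure[: k + 1])
    exp = HalfCycle("expiration", breath.volume[k:], breath.pressure[k:])
    return insp, exp
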