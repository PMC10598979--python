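"""End-to-end classification of a waveform record.

Wires breath segmentation, model-variance calibration, piecewise-fit model
selection and the typing rules into a single reproducible pass.  The model
variance sigma^2 is warm-started from the first breaths of the record (median
of per-half RSSE_2/(N-4), robust to asynchrony contamination) and then
maintained as a rolling mean over recent breaths whose selected model was
two-segment on both halves — the running definition of "non-asynchronous".
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .regression import (
    SIGMA2_FLOOR,
    UnfittableError,
    VarianceCalibration,
    fit_piecewise,
    select_model,
)
from .rules import BreathClassification, RuleConfig, classify_breath
from .waveform import BreathCycle, WaveformRecord, segment_breaths, split_half_cycles

__all__ = ["PipelineConfig", "classify_record", "classify_breaths"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the full detection pipeline."""

    alpha: float = 0.01
    r_max: int = 5
    min_segment_points: int = 5
    max_candidates: int | None = None
    crit_method: str = "chi2-bonferroni"
    calibration_breaths: int = 20      # warm-up window
    calibration_window: int = 50       # rolling window of r=2 breaths
    min_insp_duration: float = 0.05
    flow_threshold: float = 0.01
    rules: RuleConfig = field(default_factory=RuleConfig)


def _half_rsse_rate(half, cfg: PipelineConfig) -> float | None:
    n = half.n_points
    if n <= 4 or n < 2 * cfg.min_segment_points:
        return None
    try:
        fit = fit_piecewise(half, 2, cfg.min_segment_points, cfg.max_candidates)
    except UnfittableError:
        return None
    return fit.rsse / (n - 4)


def _warmup_sigma2(breaths: list[BreathCycle], cfg: PipelineConfig) -> VarianceCalibration:
    rates = []
    for breath in breaths[: cfg.calibration_breaths]:
        if not breath.fittable:
            continue
        for half in split_half_cycles(breath):
            r = _half_rsse_rate(half, cfg)
            if r is not None:
                rates.append(r)
    if not rates:
        return VarianceCalibration(SIGMA2_FLOOR, 0, "median")
    return VarianceCalibration(
        max(float(np.median(rates)), SIGMA2_FLOOR), len(rates), "median"
    )


def classify_breaths(
    breaths: list[BreathCycle],
    cfg: PipelineConfig | None = None,
) -> list[BreathClassification]:
    """Classify segmented breaths with rolling variance calibration."""
    cfg = cfg or PipelineConfig()
    calib = _warmup_sigma2(breaths, cfg)
    rolling: deque = deque(maxlen=cfg.calibration_window)
    results: list[BreathClassification] = []

    for breath in breaths:
        if not breath.fittable:
            results.append(BreathClassification(
                breath.breath_index, "none", (), None, None, {"unfittable": True}
            ))
            continue
        insp_half, exp_half = split_half_cycles(breath)
        fits = []
        for half in (insp_half, exp_half):
            if half.n_points < 2 * cfg.min_segment_points:
                fits.append(None)
                continue
            try:
                fits.append(select_model(
                    half, calib,
                    alpha=cfg.alpha, r_max=cfg.r_max,
                    min_segment_points=cfg.min_segment_points,
                    max_candidates=cfg.max_candidates,
                    crit_method=cfg.crit_method,
                ))
            except UnfittableError:
                fits.append(None)
        insp_fit, exp_fit = fits
        results.append(classify_breath(insp_fit, exp_fit, breath, cfg.rules))

        # refresh sigma^2 from breaths that selected the two-segment model
        if insp_fit is not None and exp_fit is not None \
                and insp_fit.r == 2 and exp_fit.r == 2:
            for half in (insp_half, exp_half):
                r = _half_rsse_rate(half, cfg)
                if r is not None:
                    rolling.append(r)
            if len(rolling) >= 10:
                calib = VarianceCalibration(
                    max(float(np.mean(rolling)), SIGMA2_FLOOR),
                    len(rolling), "rolling-mean",
                )
    return results


def classify_record(
    record: WaveformRecord,
    cfg: PipelineConfig | None = None,
    volume: np.ndarray | None = None,
) -> tuple[list[BreathCycle], list[BreathClassification]]:
    """Segment a record into breaths and classify each one."""
    cfg = cfg or PipelineConfig()
    breaths = segment_breaths(
        record,
        min_insp_duration=cfg.min_insp_duration,
        flow_threshold=cfg.flow_threshold,
        volume=volume,
    )
    return breaths, classify_breaths(breaths, cfg)
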