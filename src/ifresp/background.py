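"""Correction of measurements for microbial background respiration.

Microbes in the water and on chamber surfaces consume oxygen alongside the
animal, inflating apparent uptake.  Blank tests (animal-free runs) estimate
the background depletion slope per chamber; six methods then decide what
background rate to subtract from each measurement phase:

``pre.test`` / ``post.test``
    the slope of the blank run before / after the experiment, constant in time;
``average``
    the arithmetic mean of the pre and post slopes;
``linear`` / ``exponential``
    interpolation between the pre and post slopes, linear or log-linear in
    normalised time τ (τ=0 at the start of the first retained measurement
    phase, τ=1 at the end of the last), evaluated at each phase's midpoint —
    the exponential form suits growing microbial populations;
``parallel``
    the slope of an empty chamber running concurrently, fitted independently
    for every measurement phase.

The correction is applied pointwise to the trace (a linear tilt of b·Δt is
removed within each measurement phase), so a phase's corrected slope equals
its raw slope minus the background slope, for any fitting window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, MeasurementSet

__all__ = [
    "BackgroundModel",
    "METHODS",
    "fit_background",
    "build_background_model",
    "background_at",
    "correct_measurements",
    "background_percent",
]

METHODS = ("pre.test", "post.test", "average", "linear", "exponential", "parallel")

LOW_R2_WARN = 0.9  # a sloppy blank fit is a sign of an unstable system


def ols_slope_per_hour(t_s: np.ndarray, o2: np.ndarray) -> tuple[float, float, float]:
    """OLS slope of O2 vs time, scaled to per-hour; returns (slope, intercept, r2).

    Zero variance in O2 (a perfectly flat trace) carries no uptake signal;
    its slope is 0 and its r² is defined as 0 so it can never pass a
    linearity filter.  Constant time is degenerate and raises.
    """
    t_s = np.asarray(t_s, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    if len(t_s) < 2:
        raise DataError(f"need at least 2 points to fit a slope, got {len(t_s)}")
    if np.ptp(t_s) == 0:
        raise DataError("degenerate phase: all points share one timestamp")
    if np.ptp(o2) == 0:
        return 0.0, float(o2[0]), 0.0
    fit = stats.linregress(t_s, o2)
    return float(fit.slope) * 3600.0, float(fit.intercept), float(fit.rvalue) ** 2


@dataclass(frozen=True)
class BackgroundModel:
    """Per-chamber background slopes plus the rule for evaluating them in time.

    Slopes are in (do_unit/L)/h.  ``time_anchor_start``/``_end`` bound the
    normalised clock used by the interpolating methods; they are stamped on
    by :func:`correct_measurements` from the measurement set itself.
    ``parallel_slopes`` (phase label → slope) is filled during parallel
    correction.  Method ``precomputed`` marks a model reloaded from disk
    whose per-phase corrections are already known.
    """

    method: str
    pre_slope: dict[str, float] | None = None
    post_slope: dict[str, float] | None = None
    blank_chamber: str | None = None
    time_anchor_start: pd.Timestamp | None = None
    time_anchor_end: pd.Timestamp | None = None
    parallel_slopes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS + ("precomputed",):
            raise DataError(f"unknown correction method {self.method!r}; choose from {METHODS}")
        need_pre = self.method in ("pre.test", "average", "linear", "exponential")
        need_post = self.method in ("post.test", "average", "linear", "exponential")
        if need_pre and self.pre_slope is None:
            raise DataError(f"method {self.method!r} requires a pre-test")
        if need_post and self.post_slope is None:
            raise DataError(f"method {self.method!r} requires a post-test")
        if self.method == "parallel" and self.blank_chamber is None:
            raise DataError("method 'parallel' requires blank_chamber")
        for slopes in (self.pre_slope, self.post_slope):
            if slopes is not None and not all(np.isfinite(list(slopes.values()))):
                raise DataError("background slopes must be finite")
        if self.method == "exponential":
            for ch in self.pre_slope:
                pre, post = self.pre_slope[ch], self.post_slope.get(ch)
                if post is None:
                    raise DataError(f"chamber {ch}: post-test slope missing")
                if pre == 0 or post == 0 or np.sign(pre) != np.sign(post):
                    raise DataError(
                        f"chamber {ch}: exponential interpolation needs same-signed, "
                        f"non-zero pre/post slopes (got {pre:g}, {post:g}); use 'linear'"
                    )


def fit_background(test: MeasurementSet) -> pd.DataFrame:
    """Fit per-chamber background slopes over a blank test's measurement phase(s).

    Returns a frame indexed by chamber id with ``slope`` ((do_unit/L)/h) and
    ``r2`` columns.  Multiple test phases are pooled into one fit per chamber
    (time measured from the start of each phase).
    """
    if test.kind != "background_test":
        raise DataError("fit_background expects a background-test set")
    rows = {}
    for ch in test.info.chamber_ids:
        ts, o2s = [], []
        for span in test.measurement_phases:
            sub = test.chamber_phase_values(ch, span.label)
            ts.append(sub["t_s"].to_numpy())
            o2s.append(sub["o2"].to_numpy())
        t = np.concatenate(ts)
        o2 = np.concatenate(o2s)
        slope, _, r2 = ols_slope_per_hour(t, o2)
        if r2 < LOW_R2_WARN and np.ptp(o2) > 0:
            warnings.warn(
                f"background fit for {ch} has r²={r2:.3f} < {LOW_R2_WARN}; "
                "the blank trace may be unstable"
            )
        rows[ch] = {"slope": slope, "r2": r2}
    return pd.DataFrame.from_dict(rows, orient="index")


def build_background_model(
    method: str,
    pre: MeasurementSet | None = None,
    post: MeasurementSet | None = None,
    blank_chamber: str | None = None,
) -> BackgroundModel:
    """Fit the supplied blank tests and assemble a BackgroundModel."""
    pre_slope = fit_background(pre)["slope"].to_dict() if pre is not None else None
    post_slope = fit_background(post)["slope"].to_dict() if post is not None else None
    return BackgroundModel(
        method=method, pre_slope=pre_slope, post_slope=post_slope, blank_chamber=blank_chamber
    )


def background_at(
    model: BackgroundModel,
    phase_midtime: pd.Timestamp,
    chamber: str,
    phase: str | None = None,
) -> float:
    """Background slope ((do_unit/L)/h) for one chamber at one moment.

    For the interpolating methods the midtime is mapped to τ ∈ [0, 1] between
    the model's time anchors (clamped, with a warning, outside them).  For
    ``parallel`` the per-phase blank slope is looked up by phase label.
    """
    if model.method == "pre.test":
        return model.pre_slope[chamber]
    if model.method == "post.test":
        return model.post_slope[chamber]
    if model.method == "average":
        return 0.5 * (model.pre_slope[chamber] + model.post_slope[chamber])
    if model.method == "parallel":
        if phase is None or phase not in model.parallel_slopes:
            raise DataError(
                "parallel background lookup needs a phase label fitted during correction"
            )
        return model.parallel_slopes[phase]
    if model.method == "precomputed":
        raise DataError("a precomputed model only supports already-corrected data")
    if model.time_anchor_start is None or model.time_anchor_end is None:
        raise DataError("interpolating methods need time anchors (set during correction)")
    span = (model.time_anchor_end - model.time_anchor_start).total_seconds()
    tau = (pd.Timestamp(phase_midtime) - model.time_anchor_start).total_seconds() / span
    if tau < 0 or tau > 1:
        warnings.warn(f"phase midtime outside the measurement span (τ={tau:.3f}); clamping")
        tau = min(max(tau, 0.0), 1.0)
    pre, post = model.pre_slope[chamber], model.post_slope[chamber]
    if model.method == "linear":
        return pre + (post - pre) * tau
    # exponential: log-linear in τ, b(τ) = pre · (post/pre)^τ
    return pre * (post / pre) ** tau


def correct_measurements(meas: MeasurementSet, model: BackgroundModel) -> MeasurementSet:
    """Subtract the background tilt from every measurement phase.

    Within each phase, corrected O2(t) = raw O2(t) − b·(t − t_start), with b
    evaluated at the phase's temporal midpoint (or fitted on the blank
    chamber for the same phase, for ``parallel``).  The raw series is kept in
    ``<chamber>.raw`` columns for QC comparison.
    """
    if meas.corrected:
        raise DataError("measurement set is already corrected")
    if meas.kind != "measurement":
        raise DataError("correct_measurements expects a measurement set")
    for slopes in (model.pre_slope, model.post_slope):
        if slopes is not None:
            missing = [c for c in meas.info.chamber_ids if c not in slopes]
            if missing:
                raise DataError(f"background model lacks slopes for chambers {missing}")
    if model.method == "parallel":
        meas.info.chamber(model.blank_chamber)

    spans = meas.measurement_phases
    if not spans:
        raise DataError("no measurement phases to correct")
    model = replace(
        model,
        time_anchor_start=spans[0].start,
        time_anchor_end=spans[-1].end,
    )
    if model.method == "parallel":
        par = dict(model.parallel_slopes)
        for span in spans:
            sub = meas.chamber_phase_values(model.blank_chamber, span.label)
            slope, _, _ = ols_slope_per_hour(sub["t_s"], sub["o2"])
            par[span.label] = slope
        model = replace(model, parallel_slopes=par)

    data = meas.data.copy()
    for ch in meas.info.chamber_ids:
        data[f"{ch}.raw"] = data[ch]
    phase_background: dict[tuple[str, str], float] = {}
    for span in spans:
        mask = data["phase"] == span.label
        dt_h = (data.loc[mask, "time"] - span.start).dt.total_seconds() / 3600.0
        for ch in meas.info.chamber_ids:
            b = background_at(model, span.midtime, ch, phase=span.label)
            phase_background[(ch, span.label)] = b
            data.loc[mask, ch] = data.loc[mask, ch] - b * dt_h
    return MeasurementSet(
        info=meas.info,
        data=data,
        kind="measurement",
        corrected=True,
        background=model,
        phase_background=phase_background,
        removed=meas.removed,
    )


def background_percent(raw_slope: float, b: float) -> float:
    """Background share of total uptake, 100·b/raw_slope (% of total).

    Both slopes are normally negative, giving a positive percentage; an
    essentially zero raw slope makes the share undefined (NaN).
    """
    scale = max(1.0, abs(b))
    if abs(raw_slope) < 1e-12 * scale:
        return float("nan")
    return 100.0 * b / raw_slope
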