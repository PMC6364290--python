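"""Per-phase slope extraction, filtering, selection and regression diagnostics.

Oxygen uptake within a sealed measurement phase is summarised by the OLS
slope of O2 concentration against time over the first ``window_s`` seconds
of the phase (the window is always anchored at the phase start).  Records
failing the linearity filter (r² below threshold, default 0.95) are
discarded; survivors are then selected per chamber: all of them, the
``n_slope`` with the smallest or largest uptake, or those at or below a
given quantile of uptake.  Uptake is defined as −slope, so "min" selects
the phases with the least oxygen consumption — the standard-metabolic-rate
use case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import background_percent, ols_slope_per_hour
from .core import DataError, MeasurementSet, PhaseSpan

__all__ = [
    "SlopeRecord",
    "SlopeTable",
    "fit_phase_slope",
    "extract_slopes",
    "regression_diagnostics",
    "remove_phase",
    "activity_series",
]

DEFAULT_R2 = 0.95

SELECTION_METHODS = ("all", "min", "max", "quantile")


@dataclass(frozen=True)
class SlopeRecord:
    chamber_id: str
    phase_label: str
    slope: float        # corrected slope, (do_unit/L)/h (≤ 0 expected)
    r2: float
    window_s: float
    n_points: int
    phase_midtime: pd.Timestamp
    background_b: float  # background slope subtracted for this phase
    raw_slope: float     # slope before background correction = slope + background_b

    @property
    def uptake(self) -> float:
        return -self.slope


@dataclass
class SlopeTable:
    """Fitted slope records plus the filter/selection settings that produced them.

    ``records`` holds every fitted phase; ``selected`` the subset that passed
    the r² filter and the selection rule.  Downstream rate calculation uses
    ``selected`` only.
    """

    info: object  # ExperimentInfo; kept duck-typed to avoid a hard core import cycle
    records: list[SlopeRecord]
    selected: list[SlopeRecord]
    selection_method: str
    r2_threshold: float
    n_requested: int | None = None
    quantile_p: float | None = None

    def frame(self, selected_only: bool = True) -> pd.DataFrame:
        recs = self.selected if selected_only else self.records
        return pd.DataFrame([r.__dict__ for r in recs])


def fit_phase_slope(
    meas: MeasurementSet,
    chamber: str,
    phase: str,
    window_s: float | None = None,
) -> SlopeRecord:
    """Fit one chamber's O2 decline in one measurement phase.

    ``window_s`` restricts the fit to the first ``window_s`` seconds of the
    phase (half-open: points with t − t_start < window_s); ``None`` uses the
    full phase.
    """
    span = meas.phase(phase)
    if not span.is_measurement:
        raise DataError(f"phase {phase!r} is not a measurement phase")
    sub = meas.chamber_phase_values(chamber, phase)
    if window_s is not None:
        if window_s > span.duration_s + 1:
            raise DataError(
                f"window {window_s}s exceeds phase {phase} duration {span.duration_s:.0f}s"
            )
        sub = sub[sub["t_s"] < window_s]
    if len(sub) < 2:
        raise DataError(f"{chamber}/{phase}: fewer than 2 usable points in window")
    slope, _, r2 = ols_slope_per_hour(sub["t_s"].to_numpy(), sub["o2"].to_numpy())
    b = meas.phase_background.get((chamber, phase), 0.0)
    return SlopeRecord(
        chamber_id=chamber,
        phase_label=phase,
        slope=slope,
        r2=r2,
        window_s=float(window_s) if window_s is not None else span.duration_s,
        n_points=len(sub),
        phase_midtime=span.midtime,
        background_b=b,
        raw_slope=slope + b,
    )


def _select(records: list[SlopeRecord], method: str, n_slope, p) -> list[SlopeRecord]:
    """Apply the selection rule to one chamber's surviving records.

    Ties in uptake are broken by phase order (earlier phase wins), which the
    stable sort below guarantees because records arrive in time order.
    """
    if method == "all":
        return records
    if method == "quantile":
        uptakes = np.array([r.uptake for r in records])
        q = float(np.quantile(uptakes, p))  # linear interpolation, the type-7 rule
        return [r for r in records if r.uptake <= q]
    if n_slope is None:
        raise DataError(f"method {method!r} requires n_slope")
    if n_slope > len(records):
        warnings.warn(
            f"requested {n_slope} slopes but only {len(records)} passed the filter; "
            "returning all survivors"
        )
        n_slope = len(records)
    key = (lambda r: r.uptake) if method == "min" else (lambda r: -r.uptake)
    return sorted(records, key=key)[:n_slope]


def extract_slopes(
    meas: MeasurementSet,
    method: str = "all",
    n_slope: int | None = None,
    p: float | None = None,
    r2: float = DEFAULT_R2,
    window_s: float | None = None,
) -> SlopeTable:
    """Fit, filter and select per-phase slopes for every chamber."""
    if method not in SELECTION_METHODS:
        raise DataError(f"unknown selection method {method!r}; choose from {SELECTION_METHODS}")
    if method == "quantile":
        if p is None or not (0 <= p <= 1):
            raise DataError("method 'quantile' requires p in [0, 1]")
    if not meas.corrected:
        warnings.warn("extracting slopes from an uncorrected measurement set")
    all_records: list[SlopeRecord] = []
    selected: list[SlopeRecord] = []
    for ch in meas.info.chamber_ids:
        fitted = []
        for span in meas.measurement_phases:
            if not meas.is_usable(ch, span.label):
                continue
            fitted.append(fit_phase_slope(meas, ch, span.label, window_s))
        survivors = [r for r in fitted if r.r2 >= r2]
        all_records.extend(fitted)
        if not survivors:
            detail = ", ".join(f"{r.phase_label}: r²={r.r2:.3f}" for r in fitted) or "no usable phases"
            raise DataError(f"chamber {ch}: no slopes pass r² ≥ {r2} ({detail})")
        selected.extend(_select(survivors, method, n_slope, p))
    return SlopeTable(
        info=meas.info,
        records=all_records,
        selected=selected,
        selection_method=method,
        r2_threshold=r2,
        n_requested=n_slope,
        quantile_p=p,
    )


# ---------------------------------------------------------------------------
# Diagnostics

@dataclass(frozen=True)
class WindowFit:
    window_s: float
    slope: float
    intercept: float
    r2: float
    t_s: np.ndarray
    o2: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    std_residuals: np.ndarray
    leverage: np.ndarray


@dataclass(frozen=True)
class Diagnostics:
    chamber_id: str
    phase_label: str
    current: WindowFit
    alternative: WindowFit


def _window_fit(sub: pd.DataFrame, window_s: float) -> WindowFit:
    sub = sub[sub["t_s"] < window_s]
    t = sub["t_s"].to_numpy(dtype=float)
    o2 = sub["o2"].to_numpy(dtype=float)
    slope_h, intercept, r2 = ols_slope_per_hour(t, o2)
    fitted = intercept + slope_h / 3600.0 * t
    resid = o2 - fitted
    n = len(t)
    tbar = t.mean()
    sxx = np.sum((t - tbar) ** 2)
    leverage = 1.0 / n + (t - tbar) ** 2 / sxx if sxx > 0 else np.full(n, 1.0 / n)
    dof = max(n - 2, 1)
    s = np.sqrt(np.sum(resid**2) / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        std_resid = np.where(s > 0, resid / (s * np.sqrt(np.clip(1 - leverage, 1e-12, None))), 0.0)
    return WindowFit(window_s, slope_h, intercept, r2, t, o2, fitted, resid, std_resid, leverage)


def regression_diagnostics(
    record: SlopeRecord,
    meas: MeasurementSet,
    alt_window_s: float,
) -> Diagnostics:
    """Residual/leverage diagnostics for the current and an alternative window.

    Mirrors the linear-model diagnostic panel used to judge whether
    shortening the measurement window rescues a phase distorted late in the
    measurement (e.g. an animal that stopped swimming).
    """
    span = meas.phase(record.phase_label)
    if alt_window_s > span.duration_s + 1:
        raise DataError(
            f"alternative window {alt_window_s}s exceeds phase duration {span.duration_s:.0f}s"
        )
    sub = meas.chamber_phase_values(record.chamber_id, record.phase_label)
    return Diagnostics(
        chamber_id=record.chamber_id,
        phase_label=record.phase_label,
        current=_window_fit(sub, record.window_s),
        alternative=_window_fit(sub, alt_window_s),
    )


def plot_diagnostics(diag: Diagnostics, path=None):
    """Render the two-window diagnostic panel (trace + fits, residuals, QQ)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as _st

    fig, axes = plt.subplots(3, 2, figsize=(9, 10))
    top = axes[0, 0]
    top.plot(diag.current.t_s, diag.current.o2, ".", ms=2, color="grey")
    for fit, colour in ((diag.current, "black"), (diag.alternative, "red")):
        top.plot(fit.t_s, fit.fitted, color=colour, label=f"{fit.window_s:.0f}s r²={fit.r2:.3f}")
    top.set_xlabel("time (s)")
    top.set_ylabel("O2")
    top.set_title(f"{diag.chamber_id} {diag.phase_label}")
    top.legend()
    axes[0, 1].axis("off")
    for row, fit in ((1, diag.current), (2, diag.alternative)):
        axes[row, 0].scatter(fit.fitted, fit.residuals, s=4)
        axes[row, 0].axhline(0.0, color="grey", lw=0.5)
        axes[row, 0].set_xlabel("fitted")
        axes[row, 0].set_ylabel("residuals")
        _st.probplot(fit.std_residuals, plot=axes[row, 1])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def remove_phase(meas: MeasurementSet, chamber: str, phase: str) -> MeasurementSet:
    """Mark one chamber's points in one phase unusable; other chambers untouched."""
    return meas.with_removed(chamber, phase)


def activity_series(meas: MeasurementSet, density: float = 1000.0, compare: bool = False) -> pd.DataFrame:
    """Unfiltered per-phase mass-specific MO2 per fish, in time order.

    Used for activity inspection (is the animal settled?) and — with
    ``compare`` — for the corrected-versus-uncorrected comparison; no r²
    filter is applied.  When the background slope is negative, the corrected
    uptake is lower than the uncorrected one.
    """
    from .rates import mass_specific_mo2  # local import: rates also consumes SlopeTable

    rows = []
    for ch in meas.info.chamber_ids:
        chamber = meas.info.chamber(ch)
        for span in meas.measurement_phases:
            if not meas.is_usable(ch, span.label):
                continue
            rec = fit_phase_slope(meas, ch, span.label)
            row = {
                "chamber_id": ch,
                "animal_id": chamber.animal_id,
                "phase": span.label,
                "midtime": span.midtime,
                "mo2_mass": mass_specific_mo2(rec.slope, chamber, density),
            }
            if compare:
                row["mo2_mass_uncorrected"] = mass_specific_mo2(rec.raw_slope, chamber, density)
            rows.append(row)
    return pd.DataFrame(rows)
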