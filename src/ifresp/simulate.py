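"""Synthetic intermittent-flow experiments with known ground truth.

The generator writes generic-format logger files that emulate a multichannel
respirometry run: repeated flush/wait/measurement cycles, a linear O2
decline during sealed measurement phases driven by the animal's true
mass-specific MO2 plus a time-varying microbial background, exponential
relaxation toward air saturation during flushes, Gaussian sensor noise and
temperature jitter, and optionally injected artefacts (a leaking chamber, a
briefly blocked sensor, an animal that stops swimming mid-phase).

Within each measurement phase the total depletion rate is held constant at
animal slope + background evaluated at the phase midpoint, which makes
noise-free recovery by the matching correction method exact — the
ground-truth table emitted alongside the trace records exactly those
per-phase rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ChamberInfo, DataError
from .logger_io import write_generic
from .units import WaterConditions, o2_saturation_concentration

__all__ = ["BackgroundSpec", "Artefact", "SimSpec", "generate_experiment", "generate_background_test"]

FLUSH_TAU_S = 60.0  # relaxation time of the flush-phase return to saturation


@dataclass(frozen=True)
class BackgroundSpec:
    """Microbial background O2 depletion, (do_unit/L)/h (negative = consumption).

    ``model`` fixes how the rate moves from ``start_rate`` (at the start of
    the first measurement phase) to ``end_rate`` (at the end of the last):
    constant, linear growth, or exponential (log-linear) growth.
    """

    model: str = "constant"
    start_rate: float = 0.0
    end_rate: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("constant", "linear", "exponential"):
            raise DataError(f"unknown background model {self.model!r}")
        if self.end_rate is None:
            object.__setattr__(self, "end_rate", self.start_rate)
        if not (np.isfinite(self.start_rate) and np.isfinite(self.end_rate)):
            raise DataError("background rates must be finite")
        if self.model == "exponential":
            if self.start_rate == 0 or self.end_rate == 0 or (
                math.copysign(1, self.start_rate) != math.copysign(1, self.end_rate)
            ):
                raise DataError("exponential background needs same-signed non-zero rates")

    def rate_at(self, tau: float) -> float:
        """Background rate at normalised time τ ∈ [0, 1] over the measurement span."""
        tau = min(max(tau, 0.0), 1.0)
        if self.model == "constant":
            return self.start_rate
        if self.model == "linear":
            return self.start_rate + (self.end_rate - self.start_rate) * tau
        return self.start_rate * (self.end_rate / self.start_rate) ** tau


@dataclass(frozen=True)
class Artefact:
    """A scripted disturbance in one chamber's measurement phase.

    kinds: ``swim_stop`` (uptake drops to 20% after onset — upward
    inflection), ``blocked_sensor`` (sharp transient dip in the reading),
    ``leak`` (depletion rate decays toward zero after onset).
    """

    kind: str
    chamber: str
    phase: int  # 1-based measurement-cycle index
    onset_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("swim_stop", "blocked_sensor", "leak"):
            raise DataError(f"unknown artefact kind {self.kind!r}")


@dataclass(frozen=True)
class SimSpec:
    chambers: tuple[ChamberInfo, ...]
    true_mo2: tuple[float, ...]  # mass-specific, (do_unit)/kg/h, one per chamber
    flush_s: int = 420
    wait_s: int = 180
    measure_s: int = 1200
    n_cycles: int = 8
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    noise_sd: float = 0.0
    temperature: float = 16.5
    temp_jitter_sd: float = 0.05
    do_unit: str = "mg/L"
    o2_start: float | None = None  # default: air saturation at `temperature`
    sample_dt_s: int = 1
    start_time: str = "01/06/2020 20:00:00"
    seed: int = 0
    artefacts: tuple[Artefact, ...] = ()

    def __post_init__(self) -> None:
        if min(self.flush_s, self.wait_s, self.measure_s, self.sample_dt_s) <= 0:
            raise DataError("phase durations and sample interval must be positive")
        if self.n_cycles < 1:
            raise DataError("need at least one cycle")
        if len(self.true_mo2) != len(self.chambers):
            raise DataError("one true_mo2 value per chamber required")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if not all(np.isfinite(self.true_mo2)):
            raise DataError("true_mo2 must be finite")

    @property
    def cycle_s(self) -> int:
        return self.flush_s + self.wait_s + self.measure_s

    @property
    def saturation(self) -> float:
        if self.o2_start is not None:
            return self.o2_start
        return o2_saturation_concentration(WaterConditions(self.temperature))

    def animal_slope(self, i: int) -> float:
        """True animal depletion slope for chamber i, (do_unit/L)/h (negative)."""
        ch = self.chambers[i]
        return -self.true_mo2[i] * (ch.mass / 1000.0) / ch.effective_volume_l


def _phase_grid(spec: SimSpec):
    """Per-cycle phase boundaries in seconds from run start."""
    for c in range(spec.n_cycles):
        t0 = c * spec.cycle_s
        yield c + 1, t0, t0 + spec.flush_s, t0 + spec.flush_s + spec.wait_s, (c + 1) * spec.cycle_s


def _measurement_span(spec: SimSpec) -> tuple[float, float]:
    """Start of the first and end of the last measurement phase (seconds).

    The last recorded sample of a phase sits one sample interval before the
    phase boundary, matching the written trace.
    """
    first = spec.flush_s + spec.wait_s
    last = spec.n_cycles * spec.cycle_s - spec.sample_dt_s
    return float(first), float(last)


def _phase_backgrounds(spec: SimSpec) -> list[float]:
    """Background rate of each measurement phase, evaluated at its midpoint."""
    m0, m1 = _measurement_span(spec)
    out = []
    for _, t0, f_end, m_start, t_end in _phase_grid(spec):
        mid = (m_start + (t_end - spec.sample_dt_s)) / 2.0
        out.append(spec.background.rate_at((mid - m0) / (m1 - m0)))
    return out


def _artefact_for(spec: SimSpec, chamber_id: str, cycle: int) -> Artefact | None:
    for a in spec.artefacts:
        if a.chamber == chamber_id and a.phase == cycle:
            return a
    return None


def _simulate_frame(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = np.random.default_rng(spec.seed)
    sat = spec.saturation
    n_ch = len(spec.chambers)
    state = np.full(n_ch, sat, dtype=float)
    bg_by_phase = _phase_backgrounds(spec)
    start = pd.Timestamp(pd.to_datetime(spec.start_time, format="%d/%m/%Y %H:%M:%S"))

    times, labels, o2_cols = [], [], [[] for _ in range(n_ch)]
    truth_rows = []
    dt = spec.sample_dt_s
    for cycle, t0, flush_end, meas_start, cycle_end in _phase_grid(spec):
        bg = bg_by_phase[cycle - 1]
        phase_state0 = state.copy()
        for t in range(t0, cycle_end, dt):
            if t < flush_end:
                label = f"F{cycle}"
                state = sat + (state - sat) * math.exp(-dt / FLUSH_TAU_S)
            elif t < meas_start:
                label = f"W{cycle}"
            else:
                label = f"M{cycle}"
                if t == meas_start:
                    phase_state0 = state.copy()
                t_in = t - meas_start
                for i, ch in enumerate(spec.chambers):
                    a_slope = spec.animal_slope(i)
                    art = _artefact_for(spec, ch.chamber_id, cycle)
                    if art is not None and art.kind == "swim_stop" and t_in >= art.onset_s:
                        # integrate the kink: full rate until onset, 20% after
                        full = (a_slope + bg) / 3600.0 * art.onset_s
                        partial = (0.2 * a_slope + bg) / 3600.0 * (t_in - art.onset_s)
                        state[i] = phase_state0[i] + full + partial
                    elif art is not None and art.kind == "leak" and t_in >= art.onset_s:
                        # animal contribution decays with a 300 s timescale after onset
                        tail = t_in - art.onset_s
                        decayed = 300.0 * (1.0 - math.exp(-tail / 300.0))
                        state[i] = phase_state0[i] + (a_slope + bg) / 3600.0 * art.onset_s \
                            + bg / 3600.0 * tail + a_slope / 3600.0 * decayed
                    else:
                        state[i] = phase_state0[i] + (a_slope + bg) / 3600.0 * t_in
            if np.any(state < 0):
                low = spec.chambers[int(np.argmin(state))].chamber_id
                raise DataError(
                    f"infeasible spec: O2 in {low} would go negative at t={t}s; "
                    "shorten phases or reduce uptake"
                )
            noise = rng.normal(0.0, spec.noise_sd, size=n_ch) if spec.noise_sd > 0 else 0.0
            reading = state + noise
            for i, ch in enumerate(spec.chambers):
                art = _artefact_for(spec, ch.chamber_id, cycle)
                if (
                    art is not None
                    and art.kind == "blocked_sensor"
                    and label.startswith("M")
                    and art.onset_s <= (t - meas_start) < art.onset_s + 60
                ):
                    # triangular dip, max 1.5 units deep, 60 s wide
                    u = ((t - meas_start) - art.onset_s) / 60.0
                    reading[i] -= 1.5 * (1.0 - abs(2 * u - 1.0))
            times.append(start + pd.Timedelta(seconds=t))
            labels.append(label)
            for i in range(n_ch):
                o2_cols[i].append(float(reading[i]))
        truth_rows.extend(
            {
                "phase": f"M{cycle}",
                "chamber_id": ch.chamber_id,
                "animal_slope": spec.animal_slope(i),
                "background_slope": bg,
                "total_slope": spec.animal_slope(i) + bg,
                "true_mo2_mass": spec.true_mo2[i],
            }
            for i, ch in enumerate(spec.chambers)
        )
    temp = spec.temperature + (
        rng.normal(0.0, spec.temp_jitter_sd, size=len(times)) if spec.temp_jitter_sd > 0 else 0.0
    )
    data = {"time": times, "phase": labels, "temp": np.round(temp, 3)}
    for i, ch in enumerate(spec.chambers):
        data[ch.chamber_id] = o2_cols[i]
    return pd.DataFrame(data), pd.DataFrame(truth_rows)


def generate_experiment(spec: SimSpec, meas_path, truth_path=None) -> pd.DataFrame:
    """Write a generic-format measurement file; return (and optionally write) ground truth.

    The truth table holds, per measurement phase and chamber, the true
    animal slope, the background slope in force, their sum (what an OLS fit
    of the noise-free trace recovers) and the true mass-specific MO2.
    Identical specs (including seed) produce byte-identical files.
    """
    df, truth = _simulate_frame(spec)
    write_generic(
        df.rename(columns={c.chamber_id: f"Ox.{i+1}" for i, c in enumerate(spec.chambers)}),
        [f"Ox.{i+1}" for i in range(len(spec.chambers))],
        meas_path,
    )
    if truth_path is not None:
        truth.to_csv(truth_path, index=False, float_format="%.9f", lineterminator="\n")
    return truth


def generate_background_test(spec: SimSpec, when: str, path) -> pd.DataFrame:
    """Write a blank (animal-free) test whose slope matches the background model.

    ``when='pre'`` uses the background rate at the start of the measurement
    span, ``'post'`` the rate at its end.  The file is a single
    flush/wait/measurement cycle in the generic format.
    """
    if when not in ("pre", "post"):
        raise DataError("when must be 'pre' or 'post'")
    rate = spec.background.rate_at(0.0 if when == "pre" else 1.0)
    blank = replace(
        spec,
        true_mo2=tuple(0.0 for _ in spec.chambers),
        background=BackgroundSpec("constant", rate),
        n_cycles=1,
        artefacts=(),
        seed=(spec.seed * 2 + (1 if when == "pre" else 2)) % (2**31 - 1),
    )
    df, truth = _simulate_frame(blank)
    write_generic(
        df.rename(columns={c.chamber_id: f"Ox.{i+1}" for i, c in enumerate(spec.chambers)}),
        [f"Ox.{i+1}" for i in range(len(spec.chambers))],
        path,
    )
    return truth
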