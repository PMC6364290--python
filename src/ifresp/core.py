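"""Domain types for intermittent-flow respirometry data.

An experiment is described by per-chamber metadata (animal, mass, chamber
volume) and a phase-labelled multichannel time series of temperature and
dissolved oxygen.  Phases follow the intermittent-flow convention: flush
(F#), wait (W#) and measurement (M#); only measurement phases, during which
the chamber is sealed, are eligible for slope fitting.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .units import canonical_unit

if TYPE_CHECKING:  # pragma: no cover
    from .background import BackgroundModel

__all__ = [
    "ChamberInfo",
    "ExperimentInfo",
    "TracePoint",
    "PhaseSpan",
    "MeasurementSet",
    "build_info",
    "segment_phases",
]

PHASE_RE = re.compile(r"^([FWM])(\d+)$")

# A phase is flagged unusable for a chamber when fewer than this fraction of
# its points carry a finite O2 reading (sensor dropouts are dropped pointwise).
MIN_USABLE_FRACTION = 0.5

SOFT_CHAMBER_LIMIT = 8  # typical multichannel systems; exceeding it only warns


class DataError(ValueError):
    """Invalid or inconsistent respirometry data."""


@dataclass(frozen=True)
class ChamberInfo:
    """One chamber: its animal, body mass (g), water volume (mL), body density (kg/m³)."""

    chamber_id: str
    animal_id: str
    mass: float
    volume: float
    density: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("mass", "volume", "density"):
            v = getattr(self, name)
            if not (v > 0 and v == v and v != float("inf")):
                raise DataError(f"{self.chamber_id}: {name} must be finite and > 0, got {v}")
        if self.effective_volume_ml <= 0:
            raise DataError(
                f"{self.chamber_id}: body displacement {self.mass * 1000.0 / self.density:.3g} mL "
                f"exceeds chamber volume {self.volume} mL"
            )

    @property
    def effective_volume_ml(self) -> float:
        """Water volume actually depleted: chamber volume minus body displacement (mL)."""
        return self.volume - self.mass * (1000.0 / self.density)

    @property
    def effective_volume_l(self) -> float:
        return self.effective_volume_ml / 1000.0


@dataclass(frozen=True)
class ExperimentInfo:
    chambers: tuple[ChamberInfo, ...]
    do_unit: str

    def __post_init__(self) -> None:
        if not self.chambers:
            raise DataError("experiment needs at least one chamber")
        ids = [c.chamber_id for c in self.chambers]
        animals = [c.animal_id for c in self.chambers]
        if len(set(ids)) != len(ids):
            raise DataError(f"duplicate chamber ids: {ids}")
        if len(set(animals)) != len(animals):
            raise DataError(f"duplicate animal ids: {animals}")
        object.__setattr__(self, "do_unit", canonical_unit(self.do_unit))
        if len(self.chambers) > SOFT_CHAMBER_LIMIT:
            warnings.warn(
                f"{len(self.chambers)} chambers exceeds the usual {SOFT_CHAMBER_LIMIT}-channel capacity",
                stacklevel=3,
            )

    @property
    def chamber_ids(self) -> list[str]:
        return [c.chamber_id for c in self.chambers]

    def chamber(self, chamber_id: str) -> ChamberInfo:
        for c in self.chambers:
            if c.chamber_id == chamber_id:
                return c
        raise DataError(f"unknown chamber {chamber_id!r}; have {self.chamber_ids}")


def build_info(
    ids: Sequence[str],
    masses: Sequence[float],
    volumes: Sequence[float],
    do_unit: str,
    density: float = 1000.0,
    chamber_ids: Sequence[str] | None = None,
) -> ExperimentInfo:
    """Assemble validated experiment metadata.

    Chambers are named CH1..CHn unless explicit ``chamber_ids`` are given;
    ``ids`` are the animal identifiers, ``masses`` in grams, ``volumes`` in mL.
    """
    if not (len(ids) == len(masses) == len(volumes)):
        raise DataError(
            f"ids/masses/volumes lengths differ: {len(ids)}/{len(masses)}/{len(volumes)}"
        )
    if chamber_ids is None:
        chamber_ids = [f"CH{i + 1}" for i in range(len(ids))]
    chambers = tuple(
        ChamberInfo(ch, str(a), float(m), float(v), float(density))
        for ch, a, m, v in zip(chamber_ids, ids, masses, volumes)
    )
    return ExperimentInfo(chambers=chambers, do_unit=do_unit)


@dataclass(frozen=True)
class TracePoint:
    """One logger row: absolute timestamp, phase label, temperature, per-chamber O2."""

    timestamp: pd.Timestamp
    phase_label: str
    temperature: float
    o2: tuple[float, ...]


@dataclass(frozen=True)
class PhaseSpan:
    label: str
    start: pd.Timestamp
    end: pd.Timestamp
    n_points: int

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()

    @property
    def midtime(self) -> pd.Timestamp:
        return self.start + (self.end - self.start) / 2

    @property
    def is_measurement(self) -> bool:
        return self.label.startswith("M")


def _validate_label(label: str) -> None:
    if PHASE_RE.match(str(label)) is None:
        raise DataError(f"malformed phase label {label!r} (expected F#, W# or M#)")


def segment_phases(points) -> list[PhaseSpan]:
    """Partition a trace into contiguous phases.

    Accepts a sequence of :class:`TracePoint` or a DataFrame with ``time``
    and ``phase`` columns.  Consecutive rows sharing a label form one phase;
    every point belongs to exactly one phase.  Single-point phases are kept
    (so the partition property holds) but downstream slope fitting rejects
    them.
    """
    if isinstance(points, pd.DataFrame):
        df = points
    else:
        points = list(points)
        df = pd.DataFrame(
            {
                "time": [p.timestamp for p in points],
                "phase": [p.phase_label for p in points],
            }
        )
    if df.empty:
        raise DataError("empty trace: no points to segment")
    times = pd.to_datetime(df["time"])
    if not times.is_monotonic_increasing or times.duplicated().any():
        raise DataError("timestamps must be strictly increasing")
    labels = df["phase"].astype(str)
    for lab in labels.unique():
        _validate_label(lab)
    runs = (labels != labels.shift()).cumsum()
    spans: list[PhaseSpan] = []
    for _, grp in df.groupby(runs, sort=False):
        t = pd.to_datetime(grp["time"])
        spans.append(
            PhaseSpan(
                label=str(grp["phase"].iloc[0]),
                start=t.iloc[0],
                end=t.iloc[-1],
                n_points=len(grp),
            )
        )
    return spans


@dataclass
class MeasurementSet:
    """Phase-segmented multichannel O2/temperature series plus its metadata.

    ``data`` columns: ``time`` (datetime64), ``phase`` (str), ``temp`` (°C),
    then one O2 column per chamber id, in ``info`` order.  When the set has
    been background-corrected, the pre-correction series are retained in
    ``<chamber>.raw`` columns and ``phase_background`` records the background
    slope (units/L/h) subtracted within each (chamber, phase).
    """

    info: ExperimentInfo
    data: pd.DataFrame
    kind: str  # "background_test" | "measurement"
    corrected: bool = False
    background: "BackgroundModel | None" = None
    phase_background: dict[tuple[str, str], float] = field(default_factory=dict)
    removed: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("background_test", "measurement"):
            raise DataError(f"kind must be background_test or measurement, got {self.kind!r}")
        if self.corrected and self.background is None:
            raise DataError("corrected set must reference its BackgroundModel")
        missing = [c for c in self.info.chamber_ids if c not in self.data.columns]
        if missing:
            raise DataError(f"data lacks O2 columns for chambers {missing}")

    @property
    def phases(self) -> list[PhaseSpan]:
        return segment_phases(self.data)

    @property
    def measurement_phases(self) -> list[PhaseSpan]:
        return [p for p in self.phases if p.is_measurement]

    def phase(self, label: str) -> PhaseSpan:
        for p in self.phases:
            if p.label == label:
                return p
        raise DataError(f"no phase {label!r} in this set")

    def phase_frame(self, label: str) -> pd.DataFrame:
        out = self.data[self.data["phase"] == label]
        if out.empty:
            raise DataError(f"no phase {label!r} in this set")
        return out

    def chamber_phase_values(self, chamber_id: str, label: str) -> pd.DataFrame:
        """Time (s from phase start) and finite O2 values of one chamber in one phase."""
        self.info.chamber(chamber_id)
        frame = self.phase_frame(label)
        t0 = frame["time"].iloc[0]
        sub = pd.DataFrame(
            {
                "t_s": (frame["time"] - t0).dt.total_seconds().to_numpy(),
                "o2": frame[chamber_id].to_numpy(),
            }
        )
        return sub[sub["o2"].notna()].reset_index(drop=True)

    def is_usable(self, chamber_id: str, label: str) -> bool:
        """A (chamber, phase) is usable unless removed or mostly dropouts."""
        if (chamber_id, label) in self.removed:
            return False
        frame = self.phase_frame(label)
        n_finite = int(frame[chamber_id].notna().sum())
        return n_finite >= 2 and n_finite >= MIN_USABLE_FRACTION * len(frame)

    def with_removed(self, chamber_id: str, label: str) -> "MeasurementSet":
        self.info.chamber(chamber_id)
        self.phase(label)
        return replace(self, removed=self.removed | {(chamber_id, label)})
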