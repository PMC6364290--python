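"""Metabolic-rate calculation: MO2, SMR estimators and metabolic scope.

Absolute oxygen uptake converts a depletion slope into a whole-animal rate:

    absMO2 = −(Δ[O2]/Δt) · V_eff        ('do_unit'/h)
    massMO2 = absMO2 / m                ('do_unit'/kg/h)

where Δ[O2]/Δt is the (background-corrected) slope in (do_unit/L)/h, m is
body mass in kg and V_eff is the effective water volume in litres: chamber
volume minus the animal's body displacement m/D (D = body density, default
1000 kg/m³ — at that default, V_eff in mL is simply volume(mL) − mass(g)).
Uptake is reported positive for declining O2; a rising corrected trace
yields a negative MO2 with a warning (over-correction is information, not an
error).

Standard metabolic rate is summarised from repeated mass-specific MO2
values by one of four estimators: the mean of the lowest component of a
normal mixture (MLND), a quantile of the distribution, the mean of the 10
smallest values (low10), or the mean of the smallest 10% of values
(low10pc).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .background import background_percent
from .core import ChamberInfo, DataError, ExperimentInfo
from .slopes import SlopeTable

__all__ = [
    "MRResult",
    "calculate_mr",
    "mass_specific_mo2",
    "determine_smr",
    "apply_smr_estimator",
    "metabolic_scope",
    "SMR_METHODS",
]

SMR_METHODS = ("mlnd", "quant", "low10", "low10pc")

MLND_MAX_COMPONENTS = 4
MLND_RESTARTS = 5
MLND_DEFAULT_SEED = 42


@dataclass
class MRResult:
    """Per-phase and per-fish metabolic rates for one trait.

    ``records``: one row per selected phase (slopes, background share, MO2).
    ``summary``: one row per fish with the trait's summary MO2 (mean of the
    selected phases unless an SMR estimator was applied), mean background
    share, and the chamber metadata needed for export.
    """

    trait: str
    records: pd.DataFrame
    summary: pd.DataFrame
    do_unit: str
    density: float


def _effective_volume_l(chamber: ChamberInfo, density: float) -> float:
    veff_ml = chamber.volume - chamber.mass * (1000.0 / density)
    if veff_ml <= 0:
        raise DataError(
            f"{chamber.chamber_id}: effective volume non-positive at density {density} kg/m³"
        )
    return veff_ml / 1000.0


def absolute_mo2(slope: float, chamber: ChamberInfo, density: float = 1000.0) -> float:
    """Whole-animal uptake ('do_unit'/h) from a slope in (do_unit/L)/h."""
    return -slope * _effective_volume_l(chamber, density)


def mass_specific_mo2(slope: float, chamber: ChamberInfo, density: float = 1000.0) -> float:
    return absolute_mo2(slope, chamber, density) / (chamber.mass / 1000.0)


def calculate_mr(
    slopes: SlopeTable,
    info: ExperimentInfo | None = None,
    density: float = 1000.0,
    trait: str = "MR",
) -> MRResult:
    """Convert a slope table's selected records into absolute and mass-specific MO2."""
    info = info if info is not None else slopes.info
    if not slopes.selected:
        raise DataError("slope table has no selected records")
    rows = []
    for rec in slopes.selected:
        chamber = info.chamber(rec.chamber_id)
        abs_mo2 = absolute_mo2(rec.slope, chamber, density)
        if abs_mo2 < 0:
            warnings.warn(
                f"{rec.chamber_id}/{rec.phase_label}: O2 rising after correction "
                f"(slope {rec.slope:+.4g}); MO2 reported negative"
            )
        rows.append(
            {
                "chamber_id": rec.chamber_id,
                "animal_id": chamber.animal_id,
                "phase": rec.phase_label,
                "slope": rec.slope,
                "raw_slope": rec.raw_slope,
                "r2": rec.r2,
                "window_s": rec.window_s,
                "background_b": rec.background_b,
                "bg_percent": background_percent(rec.raw_slope, rec.background_b),
                "abs_mo2": abs_mo2,
                "mass_mo2": abs_mo2 / (chamber.mass / 1000.0),
            }
        )
    records = pd.DataFrame(rows)
    over = records["bg_percent"] > 100.0
    if over.any():
        warnings.warn(
            f"{int(over.sum())} phase(s) have background exceeding total uptake (>100%)"
        )
    summary_rows = []
    for ch in info.chambers:
        sub = records[records["chamber_id"] == ch.chamber_id]
        if sub.empty:
            continue
        summary_rows.append(
            {
                "animal_id": ch.animal_id,
                "chamber_id": ch.chamber_id,
                "mass_g": ch.mass,
                "volume_ml": ch.volume,
                "do_unit": info.do_unit,
                "n_phases": len(sub),
                "smr_method": "mean",
                "mo2_abs": sub["abs_mo2"].mean(),
                "mo2_mass": sub["mass_mo2"].mean(),
                "bg_percent": sub["bg_percent"].mean(),
            }
        )
    return MRResult(
        trait=trait,
        records=records,
        summary=pd.DataFrame(summary_rows),
        do_unit=info.do_unit,
        density=density,
    )


# ---------------------------------------------------------------------------
# SMR estimators

def _mlnd(values: np.ndarray, seed: int) -> tuple[float, dict]:
    from sklearn.mixture import GaussianMixture

    x = values.reshape(-1, 1)
    best = None
    best_bic = math.inf
    max_k = min(MLND_MAX_COMPONENTS, len(values))
    for k in range(1, max_k + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=MLND_RESTARTS,
            random_state=seed,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    means = best.means_.ravel()
    low = int(np.argmin(means))
    meta = {
        "n_components": best.n_components,
        "means": np.sort(means).tolist(),
        "weights": best.weights_[np.argsort(means)].tolist(),
        "bic": float(best_bic),
    }
    return float(means[low]), meta


def determine_smr(
    values,
    method: str = "mlnd",
    p: float = 0.25,
    seed: int = MLND_DEFAULT_SEED,
) -> tuple[float, dict]:
    """Summarise repeated MO2 values into a standard metabolic rate.

    Returns (SMR, metadata).  ``mlnd`` fits normal mixtures with 1–4
    components by EM, picks the component count by BIC and returns the mean
    of the lowest-mean component; ``quant`` returns the p-quantile (linear
    interpolation between order statistics); ``low10`` the mean of the 10
    smallest values; ``low10pc`` the mean of the smallest 10% (count
    ceil(0.1·n), at least 1).  All four are permutation-invariant.
    """
    values = np.asarray(list(values), dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if method not in SMR_METHODS:
        raise DataError(f"unknown SMR method {method!r}; choose from {SMR_METHODS}")
    if method == "mlnd":
        if n < 10:
            raise DataError(f"MLND needs at least 10 values, got {n}")
        return _mlnd(values, seed)
    if method == "quant":
        if not (0 <= p <= 1):
            raise DataError("quantile level p must lie in [0, 1]")
        return float(np.quantile(values, p)), {"p": p, "n": n}
    if method == "low10":
        if n < 10:
            raise DataError(f"low10 needs at least 10 values, got {n}")
        return float(np.sort(values)[:10].mean()), {"n": n}
    # low10pc
    if n < 1:
        raise DataError("low10pc needs at least one value")
    k = max(1, math.ceil(0.10 * n))
    return float(np.sort(values)[:k].mean()), {"n": n, "k": k}


def apply_smr_estimator(
    mr: MRResult,
    method: str,
    p: float = 0.25,
    seed: int = MLND_DEFAULT_SEED,
) -> MRResult:
    """Replace each fish's summary MO2 with an SMR estimator over its phases.

    The estimator runs on mass-specific values; the absolute summary is
    rescaled consistently (the two orderings coincide per fish because the
    mass-specific transform is monotone).
    """
    summary = mr.summary.copy()
    for i, row in summary.iterrows():
        sub = mr.records[mr.records["animal_id"] == row["animal_id"]]
        smr_mass, _ = determine_smr(sub["mass_mo2"], method=method, p=p, seed=seed)
        summary.loc[i, "mo2_mass"] = smr_mass
        summary.loc[i, "mo2_abs"] = smr_mass * (row["mass_g"] / 1000.0)
        summary.loc[i, "smr_method"] = method
    return MRResult(
        trait=mr.trait, records=mr.records, summary=summary,
        do_unit=mr.do_unit, density=mr.density,
    )


def metabolic_scope(smr: MRResult, amr: MRResult) -> pd.DataFrame:
    """Per-fish aerobic scope: absolute (AMR−SMR, both bases) and factorial (AMR/SMR)."""
    s = smr.summary.set_index("animal_id")
    a = amr.summary.set_index("animal_id")
    for missing in sorted(set(s.index) - set(a.index)):
        raise DataError(f"animal {missing!r} missing from {amr.trait} results")
    for missing in sorted(set(a.index) - set(s.index)):
        raise DataError(f"animal {missing!r} missing from {smr.trait} results")
    rows = []
    for animal in s.index:
        smr_mass, amr_mass = s.loc[animal, "mo2_mass"], a.loc[animal, "mo2_mass"]
        factorial = amr_mass / smr_mass if smr_mass > 0 else float("nan")
        if not smr_mass > 0:
            warnings.warn(f"animal {animal!r}: non-positive SMR, factorial scope undefined")
        rows.append(
            {
                "animal_id": animal,
                "scope_abs": a.loc[animal, "mo2_abs"] - s.loc[animal, "mo2_abs"],
                "scope_mass": amr_mass - smr_mass,
                "scope_factorial": factorial,
            }
        )
    return pd.DataFrame(rows)
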