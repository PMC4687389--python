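"""Line-profile processing: from raw CT grayscales to concentration-vs-depth.

A :class:`LineProfile` is one scan's transect from the bath-contact surface
(x = 0) inward.  Processing composes the per-scan artifact correction, the
grayscale->HU line, and the HU->molarity conversion, and maps calendar
staining days onto *effective* staining days: the stretch between solution
exhaustion (stagnation onset) and the first solution replacement contributed
no staining and is removed from the model clock.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import (
    HUCalibration,
    ScanCalibration,
    apply_scan_correction,
    concentration_from_hu,
    hu_from_grayscale,
)
from .domain import ConcentrationField, SECONDS_PER_DAY

__all__ = [
    "LineProfile",
    "effective_day",
    "profile_to_concentration",
    "compare",
    "ComparisonSummary",
    "DEFAULT_STAGNATION_ONSET",
    "DEFAULT_REPLACEMENT_DAYS",
]

#: Day the first round of solution was effectively exhausted.
DEFAULT_STAGNATION_ONSET = 5.0
#: Days the staining solution was replaced.
DEFAULT_REPLACEMENT_DAYS = (24.0, 38.0)

CONTROL_SCAN_ID = "N"


@dataclass(frozen=True)
class LineProfile:
    """One scan's position-indexed trace.

    ``grayscale`` holds the raw scanner values; ``hu`` and ``conc`` are
    filled by :func:`profile_to_concentration`.  ``effective_day`` is the
    model time after removing the ineffective staining interval and so never
    exceeds ``actual_day``.
    """

    scan_id: str
    actual_day: float
    effective_day: float
    positions: np.ndarray
    grayscale: np.ndarray
    hu: np.ndarray | None = None
    conc: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        gs = np.asarray(self.grayscale, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "grayscale", gs)
        if pos.ndim != 1 or len(pos) < 2:
            raise ValueError("profile needs at least two positions")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(gs) != len(pos):
            raise ValueError("grayscale length must match positions")
        if self.effective_day > self.actual_day + 1e-12:
            raise ValueError("effective_day cannot exceed actual_day")
        for name in ("hu", "conc"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                object.__setattr__(self, name, arr)
                if len(arr) != len(pos):
                    raise ValueError(f"{name} length must match positions")

    @property
    def stained(self) -> bool:
        return self.scan_id != CONTROL_SCAN_ID

    def restrict(self, x_min: float, x_max: float) -> "LineProfile":
        """Sub-profile over positions in [x_min, x_max]."""
        mask = (self.positions >= x_min) & (self.positions <= x_max)
        return replace(
            self,
            positions=self.positions[mask],
            grayscale=self.grayscale[mask],
            hu=None if self.hu is None else self.hu[mask],
            conc=None if self.conc is None else self.conc[mask],
        )

    def to_frame(self):
        import pandas as pd

        data = {
            "scan_id": self.scan_id,
            "actual_day": self.actual_day,
            "position_m": self.positions,
            "grayscale": self.grayscale,
        }
        if self.hu is not None:
            data["hu"] = self.hu
        if self.conc is not None:
            data["conc_mmol_per_L"] = self.conc
        return pd.DataFrame(data)


def effective_day(
    actual_day: float,
    stagnation_onset: float = DEFAULT_STAGNATION_ONSET,
    replacement_days=DEFAULT_REPLACEMENT_DAYS,
) -> float:
    """Effective (model) staining day for a calendar staining day.

    Between the stagnation onset and the first solution replacement the bath
    was depleted and staining stalled, so calendar days in that window map to
    the onset day, and days after the replacement are shifted back by the
    window's width.  Only the first replacement defines dead time; later
    replacements kept the bath fresh.
    """
    if actual_day < 0:
        raise ValueError("actual_day must be non-negative")
    schedule = sorted(float(d) for d in replacement_days)
    if list(replacement_days) != schedule:
        raise ValueError("replacement days must be sorted ascending")
    if not schedule:
        return float(actual_day)
    first = schedule[0]
    if first < stagnation_onset:
        raise ValueError("first replacement cannot precede the stagnation onset")
    dead = first - stagnation_onset
    if actual_day <= stagnation_onset:
        return float(actual_day)
    if actual_day <= first:
        return float(stagnation_onset)
    return float(actual_day - dead)


def profile_to_concentration(
    p: LineProfile, scan_cal: ScanCalibration, hu_cal: HUCalibration
) -> LineProfile:
    """Fill ``hu`` and ``conc`` from the raw grayscales.

    Composes artifact correction, the two-anchor HU line, and the molarity
    conversion (the infiltration offset applies to stained scans only, i.e.
    every scan except the control).  Raw grayscales are left untouched.
    """
    if scan_cal.scan_id != p.scan_id:
        raise KeyError(
            f"calibration is for scan {scan_cal.scan_id!r}, profile is scan {p.scan_id!r}"
        )
    corrected = apply_scan_correction(p.grayscale, scan_cal)
    hu = hu_from_grayscale(corrected, hu_cal)
    conc = concentration_from_hu(hu, hu_cal, stained=p.stained)
    return replace(p, hu=hu, conc=conc)


@dataclass(frozen=True)
class ComparisonSummary:
    """Model-vs-observation fit summary: RMSE per profile and pooled."""

    per_profile: tuple[tuple[str, float, float], ...]  # (scan_id, effective_day, rmse)
    pooled_rmse: float
    n_points: int

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            list(self.per_profile), columns=["scan_id", "effective_day", "rmse"]
        )
        return df

    def __str__(self) -> str:
        lines = ["scan  eff.day  RMSE (mmol/L)"]
        for sid, day, rmse in self.per_profile:
            lines.append(f"{sid:>4}  {day:7.2f}  {rmse:12.4f}")
        lines.append(f"pooled RMSE over {self.n_points} points: {self.pooled_rmse:.4f}")
        return "\n".join(lines)


def compare(model: ConcentrationField, observed) -> ComparisonSummary:
    """Root-mean-square misfit between modelled total concentration and
    observed concentration profiles.

    Each profile's effective day must be among the model's output times;
    model totals are linearly interpolated to the observed positions.
    """
    rows = []
    sq_sum = 0.0
    n_total = 0
    for p in observed:
        if p.conc is None:
            raise ValueError(f"profile {p.scan_id!r} has no concentrations; convert it first")
        t = p.effective_day * SECONDS_PER_DAY
        try:
            predicted = model.interp_total(t, p.positions)
        except KeyError as exc:
            raise KeyError(
                f"profile {p.scan_id!r}: effective day {p.effective_day} not among model times"
            ) from exc
        # cell centres sit half a width inside the domain edges
        lo = model.positions[0] - model.cell_widths[0]
        hi = model.positions[-1] + model.cell_widths[-1]
        if p.positions.min() < lo - 1e-12 or p.positions.max() > hi + 1e-12:
            raise ValueError(f"profile {p.scan_id!r} extends outside the model domain")
        resid = predicted - p.conc
        rows.append((p.scan_id, float(p.effective_day), float(np.sqrt(np.mean(resid**2)))))
        sq_sum += float(np.sum(resid**2))
        n_total += len(resid)
    if n_total == 0:
        raise ValueError("no observations to compare")
    return ComparisonSummary(
        per_profile=tuple(rows),
        pooled_rmse=float(np.sqrt(sq_sum / n_total)),
        n_points=n_total,
    )
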