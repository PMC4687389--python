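"""Synthetic serial-scan generator.

Stands in for the study's five serial CT scans of a stained specimen
(control plus staining days 5/10/34/49).  The generator runs the forward
transport model at each scan's *effective* staining day and then pushes the
total concentration back through the inverse of the measurement chain:

    concentration -> HU (K factor, plus unstained-tissue baseline and, for
    stained scans, the solute-infiltration offset) -> grayscale (inverse of
    the two-anchor air/water line) -> raw grayscale (inverse of the per-scan
    affine artifact distortion) -> additive Gaussian sensor noise.

With zero noise the chain is the exact inverse of
:func:`dicequant.profiles.profile_to_concentration`, so the analysis pipeline
recovers the ground truth to interpolation error — the closure property every
downstream test leans on.  Output is reproducible: same seed, same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    HUCalibration,
    REFERENCE_SCAN_CALIBRATIONS,
    ScanCalibration,
    grayscale_from_hu,
    invert_scan_correction,
)
from .domain import ConcentrationField, SECONDS_PER_DAY, SolverConfig, ZonedDomain, reference_domain
from .profiles import CONTROL_SCAN_ID, LineProfile, effective_day
from .solver import profiles_at_scan_days

__all__ = ["SyntheticScanSpec", "generate"]

#: The study's scan schedule: control, then staining days 5, 10, 34, 49.
DEFAULT_SCHEDULE = (("N", 0.0), ("A", 5.0), ("B", 10.0), ("C", 34.0), ("D", 49.0))


def _default_distortions() -> dict[str, ScanCalibration]:
    return dict(REFERENCE_SCAN_CALIBRATIONS)


@dataclass(frozen=True)
class SyntheticScanSpec:
    """Configuration of the synthetic scan series.

    ``baseline_hu`` is the HU a zone reads before any staining; ``None``
    (default) uses ``k_factor * baseline_offset`` in every zone, which makes
    the generator exactly invert the analysis chain's offset subtraction.
    ``noise_std`` is the additive Gaussian sensor noise on raw grayscales
    (default 80, about one percent of the reference grayscale range).
    """

    truth_domain: ZonedDomain = field(default_factory=reference_domain)
    scan_schedule: tuple[tuple[str, float], ...] = DEFAULT_SCHEDULE
    hu_cal: HUCalibration = field(default_factory=HUCalibration)
    distortions: dict[str, ScanCalibration] = field(default_factory=_default_distortions)
    baseline_hu: dict[str, float] | float | None = None
    noise_std: float = 80.0
    seed: int = 0
    grid_spacing: float = 1e-4
    transect_length: float = 15e-3
    solver_config: SolverConfig | None = None

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")
        if any(day < 0 for _, day in self.scan_schedule):
            raise ValueError("schedule days must be non-negative")
        for sid, _ in self.scan_schedule:
            if sid not in self.distortions:
                raise KeyError(f"no grayscale distortion given for scan {sid!r}")

    def baseline_for(self, zone_name: str) -> float:
        if self.baseline_hu is None:
            return self.hu_cal.k_factor * self.hu_cal.baseline_offset
        if isinstance(self.baseline_hu, dict):
            return float(self.baseline_hu[zone_name])
        return float(self.baseline_hu)


def generate(spec: SyntheticScanSpec) -> tuple[list[LineProfile], ConcentrationField]:
    """Produce one raw-grayscale profile per scheduled scan plus ground truth.

    The ground-truth :class:`~dicequant.domain.ConcentrationField` holds the
    forward solution at every distinct effective day in the schedule, for use
    as the oracle in closure tests.
    """
    eff_days = {sid: effective_day(day) for sid, day in spec.scan_schedule}
    truth = profiles_at_scan_days(
        spec.truth_domain, sorted(set(eff_days.values())), spec.solver_config
    )
    n_pts = int(round(spec.transect_length / spec.grid_spacing)) + 1
    positions = np.linspace(0.0, spec.transect_length, n_pts)
    if spec.transect_length > spec.truth_domain.length:
        raise ValueError("transect extends beyond the truth domain")
    zone_names = [spec.truth_domain.zone_at(x).name for x in positions]
    baseline = np.array([spec.baseline_for(nm) for nm in zone_names])

    rng = np.random.default_rng(spec.seed)
    profiles: list[LineProfile] = []
    for sid, day in spec.scan_schedule:
        eff = eff_days[sid]
        conc = truth.interp_total(eff * SECONDS_PER_DAY, positions)
        stained = sid != CONTROL_SCAN_ID
        # per-zone baseline replaces the flat baseline-offset term of the
        # analysis chain; the infiltration offset is kept as in the chain
        hu = (
            conc * spec.hu_cal.k_factor
            + baseline
            + (spec.hu_cal.infiltration_offset * spec.hu_cal.k_factor if stained else 0.0)
        )
        gs = grayscale_from_hu(hu, spec.hu_cal)
        raw = invert_scan_correction(gs, spec.distortions[sid])
        if spec.noise_std > 0:
            raw = raw + rng.normal(0.0, spec.noise_std, size=raw.shape)
        profiles.append(
            LineProfile(
                scan_id=sid,
                actual_day=day,
                effective_day=eff,
                positions=positions,
                grayscale=raw,
            )
        )
    return profiles, truth
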