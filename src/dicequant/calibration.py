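"""CT grayscale calibration: artifact recalibration, Hounsfield units, molarity.

Serial scans of the same specimen drift in raw grayscale because of beam
hardening and helical-acquisition artifacts.  Each scan is recalibrated by
an affine map anchored on two internal reference materials — encapsulated
air and unstained brain — so that both read the same values across scans.

Corrected grayscales convert to Hounsfield units (HU) along the standard
two-anchor line (air = -1000 HU, water/formalin = 0 HU), and HU convert to
iodine molarity through the scanner's K factor (HU per mmol/L), less two
offsets: the apparent molarity of unstained fixed muscle (baseline) and, in
stained scans, a solute-infiltration offset attributed to fast-moving
potassium ions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScanCalibration",
    "HUCalibration",
    "apply_scan_correction",
    "invert_scan_correction",
    "hu_from_grayscale",
    "grayscale_from_hu",
    "k_factor_regression",
    "concentration_from_hu",
    "hu_from_concentration",
    "CalibrationError",
    "REFERENCE_SCAN_CALIBRATIONS",
    "REFERENCE_VIALS",
    "default_hu_calibration",
]


class CalibrationError(ValueError):
    """Invalid or degenerate calibration data."""


@dataclass(frozen=True)
class ScanCalibration:
    """Per-scan reference grayscales and the affine correction they induce.

    ``raw_air`` and ``raw_reference`` are the scan's measured grayscales for
    encapsulated air and unstained brain; ``raw_range`` their printed
    difference (kept separately because the source statistics were rounded
    to integers, so it can differ from the recomputed difference by one).
    ``target_air``/``target_range`` are the common values every scan in the
    group is rescaled to.
    """

    scan_id: str
    raw_air: float
    raw_reference: float
    raw_range: float
    target_air: float
    target_range: float

    def __post_init__(self) -> None:
        if self.raw_range <= 0 or self.target_range <= 0:
            raise CalibrationError(f"scan {self.scan_id!r}: grayscale ranges must be positive")
        if abs((self.raw_reference - self.raw_air) - self.raw_range) > 1.0 + 1e-9:
            raise CalibrationError(
                f"scan {self.scan_id!r}: raw_reference - raw_air must equal raw_range "
                "within integer rounding"
            )


def apply_scan_correction(raw, cal: ScanCalibration):
    """Affine artifact correction sending ``raw_air -> target_air`` and
    ``raw_air + raw_range -> target_air + target_range``.

    Equivalent to rescaling so the scan's air and brain references read the
    group-common values.
    """
    raw_arr = np.asarray(raw, dtype=float)
    out = (raw_arr - cal.raw_air) * (cal.target_range / cal.raw_range) + cal.target_air
    return float(out) if np.isscalar(raw) or raw_arr.ndim == 0 else out


def invert_scan_correction(corrected, cal: ScanCalibration):
    """Inverse of :func:`apply_scan_correction` (used when synthesising raw scans)."""
    arr = np.asarray(corrected, dtype=float)
    out = (arr - cal.target_air) * (cal.raw_range / cal.target_range) + cal.raw_air
    return float(out) if np.isscalar(corrected) or arr.ndim == 0 else out


@dataclass(frozen=True)
class HUCalibration:
    """Grayscale->HU anchors plus the HU->molarity conversion constants.

    ``k_factor`` is the scanner-specific slope of HU against iodine molarity
    (HU per mmol/L).  ``baseline_offset`` is the apparent molarity of
    unstained fixed muscle subtracted from every scan; ``infiltration_offset``
    is additionally subtracted from stained scans.
    """

    gs_air: float = 12800.0
    gs_water: float = 18202.0
    k_factor: float = 4.6
    baseline_offset: float = 150.0
    infiltration_offset: float = 50.0

    def __post_init__(self) -> None:
        if self.gs_water <= self.gs_air:
            raise CalibrationError("water grayscale anchor must exceed the air anchor")
        if self.k_factor <= 0:
            raise CalibrationError("K factor must be positive")
        if self.baseline_offset < 0 or self.infiltration_offset < 0:
            raise CalibrationError("offsets must be non-negative")


def default_hu_calibration() -> HUCalibration:
    """The study scanner's calibration (anchors from the solution-vial scan)."""
    return HUCalibration()


def hu_from_grayscale(gs, cal: HUCalibration):
    """Hounsfield units from grayscale: linear with hu(air) = -1000, hu(water) = 0."""
    arr = np.asarray(gs, dtype=float)
    out = (arr - cal.gs_water) / (cal.gs_water - cal.gs_air) * 1000.0
    return float(out) if np.isscalar(gs) or arr.ndim == 0 else out


def grayscale_from_hu(hu, cal: HUCalibration):
    """Inverse of :func:`hu_from_grayscale`."""
    arr = np.asarray(hu, dtype=float)
    out = cal.gs_water + arr * (cal.gs_water - cal.gs_air) / 1000.0
    return float(out) if np.isscalar(hu) or arr.ndim == 0 else out


def k_factor_regression(points) -> float:
    """Least-squares slope of HU on molarity (intercept fitted), HU per mmol/L.

    ``points`` is a sequence of (molarity_mmol_per_L, hu) pairs with at least
    two distinct molarities.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise CalibrationError("need at least two (molarity, HU) points")
    molarity, hu = pts[:, 0], pts[:, 1]
    if np.ptp(molarity) == 0.0:
        raise CalibrationError("all molarities identical: slope is undefined")
    slope, _ = np.polyfit(molarity, hu, 1)
    return float(slope)


def concentration_from_hu(hu, cal: HUCalibration, stained: bool):
    """Iodine molarity (mmol/L) from HU: ``hu / K - offsets``, floored at 0.

    The baseline offset is always subtracted; the infiltration offset only
    for stained scans.  Values that would go negative after the subtraction
    are floored at zero (the offsets are approximate bulk corrections).
    """
    arr = np.asarray(hu, dtype=float)
    conc = arr / cal.k_factor - cal.baseline_offset
    if stained:
        conc = conc - cal.infiltration_offset
    out = np.clip(conc, 0.0, None)
    return float(out) if np.isscalar(hu) or arr.ndim == 0 else out


def hu_from_concentration(conc, cal: HUCalibration, stained: bool):
    """HU equivalent of an iodine molarity including the offsets (no floor).

    Exact inverse of :func:`concentration_from_hu` wherever the floor is
    inactive; used by the synthetic-scan generator.
    """
    arr = np.asarray(conc, dtype=float)
    total = arr + cal.baseline_offset + (cal.infiltration_offset if stained else 0.0)
    out = total * cal.k_factor
    return float(out) if np.isscalar(conc) or arr.ndim == 0 else out


#: Per-scan reference statistics of the five serial scans (control N plus
#: staining days 5/10/34/49).  Scans N/A/B were rescaled to a common
#: air/brain-range pair, scans C/D (different reconstruction scaling) to
#: another.
REFERENCE_SCAN_CALIBRATIONS: dict[str, ScanCalibration] = {
    "N": ScanCalibration("N", 11988.0, 21532.0, 9543.0, 13192.0, 8635.0),
    "A": ScanCalibration("A", 13415.0, 21113.0, 7699.0, 13192.0, 8635.0),
    "B": ScanCalibration("B", 14174.0, 22835.0, 8661.0, 13192.0, 8635.0),
    "C": ScanCalibration("C", 14335.0, 23019.0, 8685.0, 15206.0, 8278.0),
    "D": ScanCalibration("D", 16078.0, 23950.0, 7872.0, 15206.0, 8278.0),
}

#: Solution-vial scan used for the molarity calibration: (material,
#: grayscale, HU, total iodine mmol/L).  HU for the iodine vials are the
#: values derived along the two-anchor air/formalin line in the source
#: workflow; molarity is None where not applicable.
REFERENCE_VIALS = (
    ("formalin", 18202.0, 0.0, 0.0),
    ("I2KI 1%", 21206.0, 394.0, 66.0),
    ("I2KI 3%", 24552.0, 949.0, 199.0),
    ("I2KI 6%", 28058.0, 1531.0, 398.0),
    ("I2KI 8.8%", 31978.0, 2181.0, 583.0),
    ("air", 12800.0, -1000.0, None),
)
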