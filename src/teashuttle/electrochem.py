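"""Microbial-fuel-cell power densities and cyclic-voltammetry loop areas.

MFC quantities follow Ohm's law on the measured cell voltage across a known
external resistance:

    I = V / R_ext          P_density = V * I / A_anode

reported per anode area in mW/m2.  A condition's bioelectricity-stimulating
effect is its fold amplification versus the pre-dosing blank; a fold above
2.00 is taken as evidence of electron-shuttle activity.

CV electrochemical activity is the closed-loop area between the oxidation
(forward) and reduction (reverse) sweeps,

    Area = integral over [V_L, V_H] of (i_h - i_l) dV      (uA*V),

computed by linear interpolation of both sweeps onto a common uniform
voltage grid followed by trapezoidal integration.  Serial-cycle area
profiles quantify attenuation and the cycle at which the response
stabilizes.

Note on units: the power-density scale used throughout is mW/m2 (volts
squared over ohms and square metres, times 1000); loop areas in uA*V are
reported interchangeably with uW since the two are dimensionally identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    MalformedCycleError,
    MissingReferenceError,
    NoDataError,
    NoOverlapError,
)

#: Anode contact area of the reference two-chamber cell, m2 (1.649 cm2).
DEFAULT_ANODE_AREA_M2 = 1.649e-4
#: External resistance applied for comparisons, ohm.
DEFAULT_RESISTANCE_OHM = 1000.0
#: Voltage grid step for sweep interpolation, V (10 mV).
DEFAULT_GRID_STEP_V = 0.010
#: Amplification fold above which electron-shuttle presence is inferred.
ES_AMPLIFICATION_THRESHOLD = 2.00


@dataclass
class MFCSeries:
    """Voltage time course of one dosing condition."""

    condition_id: str
    time_s: np.ndarray
    voltage_v: np.ndarray
    external_resistance_ohm: float = DEFAULT_RESISTANCE_OHM
    anode_area_m2: float = DEFAULT_ANODE_AREA_M2

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, float)
        self.voltage_v = np.asarray(self.voltage_v, float)
        if self.anode_area_m2 <= 0:
            raise ValueError("anode area must be positive")
        if self.external_resistance_ohm <= 0:
            raise ValueError("external resistance must be positive")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class PDRecord:
    """Power density of one condition, optionally blank-normalized."""

    condition_id: str
    pd_mean: float                  # mW/m2
    pd_sd: float                    # mW/m2
    amplification: float | None = None   # fold vs blank
    amplification_sd: float | None = None


@dataclass
class Voltammogram:
    """Multi-cycle CV trace; each cycle holds both sweep directions.

    ``cycles`` maps cycle index -> dict with keys ``forward`` and
    ``reverse``, each an (N, 2) array of (voltage V, current uA) samples.
    """

    cycles: dict[int, dict[str, np.ndarray]]
    v_low: float = -1.5
    v_high: float = 1.5
    scan_rate_mv_s: float = 10.0

    def __post_init__(self):
        if self.v_low >= self.v_high:
            raise ValueError("v_low must be below v_high")


@dataclass
class CVAreaProfile:
    areas: list[float]                      # uA*V per cycle, in order
    stabilization_cycle: int | None = None  # 1-based
    attenuation_ratio: float = field(default=np.nan)


def power_density(series: MFCSeries,
                  window: tuple[float, float] | None = None) -> PDRecord:
    """Mean and SD of instantaneous power density over a plateau window.

    ``window`` is a (start, end) time interval in seconds; the default uses
    the full series.  Power per sample is V^2 / (R * A), reported in mW/m2.
    """
    t, v = series.time_s, series.voltage_v
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        v = v[mask]
    if v.size == 0:
        raise NoDataError(f"empty window for {series.condition_id}")
    p = v * (v / series.external_resistance_ohm) / series.anode_area_m2
    p_mw = p * 1000.0
    sd = float(p_mw.std(ddof=1)) if p_mw.size > 1 else 0.0
    return PDRecord(series.condition_id, float(p_mw.mean()), sd)


def amplification(records: list[PDRecord],
                  blank_id: str = "blank1") -> list[PDRecord]:
    """Fill fold amplification versus the blank for every record.

    The ratio of means a/b carries a first-order propagated SD
    sqrt((sa/b)^2 + (a*sb/b^2)^2).  Anode area cancels in the ratio, so
    amplification is invariant to the area convention.
    """
    by_id = {r.condition_id: r for r in records}
    if blank_id not in by_id or by_id[blank_id].pd_mean <= 0:
        raise MissingReferenceError(f"no usable blank {blank_id!r}")
    b, sb = by_id[blank_id].pd_mean, by_id[blank_id].pd_sd
    out = []
    for r in records:
        a, sa = r.pd_mean, r.pd_sd
        amp = a / b
        amp_sd = float(np.hypot(sa / b, a * sb / b**2))
        out.append(PDRecord(r.condition_id, a, sa, amp, amp_sd))
    return out


def es_presence(record: PDRecord,
                threshold: float = ES_AMPLIFICATION_THRESHOLD) -> bool:
    """Electron-shuttle call: strictly above the amplification threshold."""
    if record.amplification is None:
        raise ValueError("amplification not computed")
    return record.amplification > threshold


def _sorted_sweep(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, float)
    order = np.argsort(pts[:, 0], kind="stable")
    v, i = pts[order, 0], pts[order, 1]
    # collapse duplicate voltages by averaging so interp is well-defined
    uv, idx = np.unique(v, return_inverse=True)
    ui = np.bincount(idx, weights=i) / np.bincount(idx)
    return uv, ui


def cv_loop_area(vgram: Voltammogram, cycle: int,
                 grid_step: float = DEFAULT_GRID_STEP_V,
                 ih_direction: str = "forward") -> float:
    """Closed-loop area of one cycle in uA*V.

    Both sweeps are linearly interpolated onto a shared uniform voltage
    grid spanning their overlap; the oxidation current i_h is taken from
    the ``ih_direction`` sweep (forward, i.e. increasing voltage, by
    convention) and the trapezoid rule integrates (i_h - i_l).
    """
    if cycle not in vgram.cycles:
        raise KeyError(f"cycle {cycle} absent")
    sweeps = vgram.cycles[cycle]
    if "forward" not in sweeps or "reverse" not in sweeps:
        raise MalformedCycleError(f"cycle {cycle} lacks a sweep direction")
    il_direction = "reverse" if ih_direction == "forward" else "forward"
    vh_, ih_ = _sorted_sweep(sweeps[ih_direction])
    vl_, il_ = _sorted_sweep(sweeps[il_direction])
    lo = max(vh_[0], vl_[0])
    hi = min(vh_[-1], vl_[-1])
    if lo >= hi:
        raise NoOverlapError("sweep voltage ranges do not overlap")
    n = max(2, int(round((hi - lo) / grid_step)) + 1)
    grid = np.linspace(lo, hi, n)
    gap = np.interp(grid, vh_, ih_) - np.interp(grid, vl_, il_)
    return float(np.trapezoid(gap, grid))


def area_profile(vgram: Voltammogram, tolerance: float = 0.02,
                 grid_step: float = DEFAULT_GRID_STEP_V) -> CVAreaProfile:
    """Per-cycle loop areas, stabilization cycle and attenuation ratio.

    The stabilization cycle is the first (1-based) cycle after which every
    successive relative area change is at most ``tolerance`` (default 2%).
    Attenuation ratio is area(last)/area(first).
    """
    order = sorted(vgram.cycles)
    if len(order) < 2:
        raise ValueError("need >=2 cycles for a profile")
    areas = [cv_loop_area(vgram, c, grid_step) for c in order]
    rel = [abs(areas[i + 1] - areas[i]) / abs(areas[i])
           if areas[i] != 0 else np.inf
           for i in range(len(areas) - 1)]
    stab = None
    for k in range(len(areas)):
        if all(r <= tolerance for r in rel[k:]):
            stab = k + 1
            break
    ratio = areas[-1] / areas[0] if areas[0] != 0 else np.nan
    return CVAreaProfile(areas, stab, float(ratio))
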