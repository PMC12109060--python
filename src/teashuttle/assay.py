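"""Plate-assay quantification: calibration fits, equivalents, %RSA, IC50.

Phytochemical contents (total polyphenols, flavonoids, condensed tannins)
are read off ordinary-least-squares calibration lines fitted to standard
dilution ladders and expressed as gallic-acid / rutin / catechin
equivalents.  Antioxidant activity comes from the DPPH radical-scavenging
assay, where

    %RSA = 100 * ((A_ctl - A_blk) - (A_spl - A_blk)) / (A_ctl - A_blk)

and the half-maximal inhibitory concentration IC50 is the concentration at
which a linear %RSA-vs-concentration fit crosses 50%.  FRAP reducing power
is expressed as Trolox equivalents through the same calibration machinery
with per-sample blank subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCurveError,
    DegenerateDesignError,
    InsufficientStandardsError,
    NonResponsiveSampleError,
    UndefinedControlError,
)

ASSAYS = ("TPC", "TFC", "TCTC", "DPPH", "FRAP")

EQUIVALENT_UNITS = {"TPC": "GAE", "TFC": "RE", "TCTC": "CE", "FRAP": "Trolox"}

PLATE_COLUMNS = ["sample_id", "role", "concentration", "replicate",
                 "absorbance"]


@dataclass
class AbsorbancePlate:
    """One plate read: tidy well table plus assay metadata.

    ``wells`` columns: sample_id, role (standard/sample/blank/control),
    concentration (mg/mL, NaN where inapplicable), replicate, absorbance.
    """

    wells: pd.DataFrame
    assay: str
    wavelength_nm: float | None = None

    def __post_init__(self):
        missing = [c for c in PLATE_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate table missing columns {missing}")
        if not np.isfinite(self.wells["absorbance"].to_numpy(float)).all():
            raise ValueError("non-finite absorbance values")

    def by_role(self, role: str) -> pd.DataFrame:
        return self.wells[self.wells["role"] == role]


@dataclass
class CalibrationCurve:
    slope: float            # AU per (mg/mL)
    intercept: float        # AU
    r_squared: float
    equivalent_unit: str


@dataclass
class IC50Result:
    ic50: float             # mg/mL
    slope: float            # % per (mg/mL)
    intercept: float        # %
    extrapolated: bool = False
    degenerate: bool = False


@dataclass
class RSAResult:
    """%RSA per tested concentration plus the fitted IC50 of the extract."""

    points: list[tuple[float, float]]   # (concentration mg/mL, %RSA)
    ic50: IC50Result = field(default=None)  # type: ignore[assignment]


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope/intercept/R^2 via the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0.0 or np.all(x == x.flat[0]):
        raise DegenerateDesignError("zero concentration variance")
    slope = float(((x - xbar) * (y - ybar)).sum()) / sxx
    intercept = ybar - slope * xbar
    ss_tot = float(((y - ybar) ** 2).sum())
    resid = y - (slope * x + intercept)
    ss_res = float((resid ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def fit_calibration(plate: AbsorbancePlate) -> CalibrationCurve:
    """OLS fit of replicate-averaged standard absorbance on concentration.

    Requires at least three distinct standard concentrations; replicates at
    each level are averaged before the regression so plate triplicates do
    not inflate the degrees of freedom.
    """
    std = plate.by_role("standard")
    levels = std.groupby("concentration")["absorbance"].mean()
    if len(levels) < 3:
        raise InsufficientStandardsError(
            f"need >=3 standard levels, got {len(levels)}")
    slope, intercept, r2 = _ols_line(levels.index.to_numpy(),
                                     levels.to_numpy())
    return CalibrationCurve(slope, intercept, r2,
                            EQUIVALENT_UNITS.get(plate.assay, ""))


def to_equivalents(absorbance: float, curve: CalibrationCurve,
                   dilution_factor: float = 1.0,
                   extract_conc_mg_per_ml: float | None = None) -> float:
    """Convert absorbance to standard-equivalent content.

    Returns mg/mL of standard equivalents scaled by the dilution factor;
    if the assayed solution's extract concentration is supplied, the result
    is instead mg equivalents per g of lyophilized extract.
    """
    if curve.slope == 0:
        raise DegenerateCurveError("zero calibration slope")
    conc = (absorbance - curve.intercept) / curve.slope * dilution_factor
    if extract_conc_mg_per_ml is not None:
        # mg equivalents per mL over g extract per mL
        conc = conc / (extract_conc_mg_per_ml / 1000.0)
    return conc


def rsa_percent(a_ctl: float, a_blk: float, a_spl: float) -> float:
    """Percent radical-scavenging activity from the three absorbances."""
    denom = a_ctl - a_blk
    if denom == 0:
        raise UndefinedControlError("control equals blank")
    return 100.0 * ((a_ctl - a_blk) - (a_spl - a_blk)) / denom


def estimate_ic50(points: list[tuple[float, float]],
                  max_extrapolation_factor: float = 2.0) -> IC50Result:
    """IC50 from a global OLS fit of %RSA on concentration.

    The fitted line must cross 50% within the observed concentration range
    extended by at most one two-fold dilution step on either side;
    crossings outside that window flag the result as extrapolated.  A flat
    response at exactly 50% everywhere is degenerate: the smallest observed
    concentration is returned with the degenerate flag set.
    """
    if len(points) < 2:
        raise NonResponsiveSampleError("need >=2 dose-response points")
    conc = np.array([p[0] for p in points], float)
    rsa = np.array([p[1] for p in points], float)
    if np.allclose(rsa, 50.0):
        return IC50Result(float(conc.min()), 0.0, 50.0, degenerate=True)
    slope, intercept, _ = _ols_line(conc, rsa)
    if slope <= 0:
        raise NonResponsiveSampleError(
            f"non-positive dose-response slope ({slope:.3g})")
    ic50 = (50.0 - intercept) / slope
    lo = conc.min() / max_extrapolation_factor
    hi = conc.max() * max_extrapolation_factor
    return IC50Result(float(ic50), slope, intercept,
                      extrapolated=not (lo <= ic50 <= hi))


def dpph_analysis(plate: AbsorbancePlate) -> RSAResult:
    """%RSA per sample concentration and the extract IC50 from one plate.

    Control and blank wells are averaged plate-wide; sample wells are
    averaged per concentration before applying the %RSA formula.
    """
    a_ctl = float(plate.by_role("control")["absorbance"].mean())
    a_blk = float(plate.by_role("blank")["absorbance"].mean())
    samples = plate.by_role("sample")
    points = []
    for conc, grp in samples.groupby("concentration"):
        a_spl = float(grp["absorbance"].mean())
        points.append((float(conc), rsa_percent(a_ctl, a_blk, a_spl)))
    points.sort()
    return RSAResult(points=points, ic50=estimate_ic50(points))


def frap_equivalents(plate: AbsorbancePlate, curve: CalibrationCurve,
                     dilution_factor: float = 1.0,
                     extract_conc_mg_per_ml: float | None = None
                     ) -> dict[str, float]:
    """Trolox equivalents per sample with per-sample blank subtraction.

    Each sample's blank wells (role ``blank`` sharing its sample_id) are
    averaged and subtracted from its reaction wells before conversion
    through the Trolox calibration line.
    """
    out: dict[str, float] = {}
    blanks = plate.by_role("blank")
    for sid, grp in plate.by_role("sample").groupby("sample_id"):
        a = float(grp["absorbance"].mean())
        sb = blanks[blanks["sample_id"] == sid]["absorbance"]
        a_blk = float(sb.mean()) if len(sb) else 0.0
        out[str(sid)] = to_equivalents(
            a - a_blk + curve.intercept, curve, dilution_factor,
            extract_conc_mg_per_ml)
    return out
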