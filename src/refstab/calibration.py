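"""Standard-curve calibration of primer amplification efficiency.

A dilution series (default 5-fold steps) regresses Ct on log10 relative
template concentration.  The slope k of that line gives the per-cycle
amplification efficiency E = 10^(-1/k) - 1, so perfect doubling chemistry
(slope -3.3219) corresponds to E = 100%.  Primers are accepted when the
efficiency lies in a band (default 90-120%) and the fit's R-squared clears a
floor (default 0.99).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "StandardCurve",
    "QCResult",
    "fit_standard_curve",
    "primer_qc",
    "read_dilution_series",
    "curves_to_frame",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class DilutionSeries:
    """Dilution points for one primer: (level, Ct) with concentration base**-level.

    ``level`` counts dilution steps from the undiluted template (level 0);
    replicate Ct at a level simply repeat the level.  At least three distinct
    levels are required for a meaningful regression.
    """

    primer: str
    points: tuple[tuple[int, float], ...]
    base: float = 5.0

    def __post_init__(self) -> None:
        if self.base <= 1:
            raise CalibrationError(f"{self.primer}: dilution base must exceed 1")
        levels = {lvl for lvl, _ in self.points}
        if len(levels) < 3:
            raise CalibrationError(
                f"{self.primer}: need >=3 distinct dilution levels, got {len(levels)}"
            )
        for lvl, ct in self.points:
            if lvl < 0:
                raise CalibrationError(f"{self.primer}: negative dilution level {lvl}")
            if not math.isfinite(ct):
                raise CalibrationError(f"{self.primer}: non-finite Ct at level {lvl}")

    @property
    def log10_concentration(self) -> list[float]:
        # level i of a b-fold series sits at relative concentration b**-i
        return [-lvl * math.log10(self.base) for lvl, _ in self.points]


@dataclass(frozen=True)
class StandardCurve:
    primer: str
    slope: float            # cycles per log10(concentration)
    intercept: float        # cycles at relative concentration 1
    r_squared: float
    efficiency: float       # fraction; 1.0 == 100%; NaN if undefined

    @property
    def efficiency_pct(self) -> float:
        return self.efficiency * 100.0


@dataclass(frozen=True)
class QCResult:
    primer: str
    passed: bool
    reasons: tuple[str, ...] = field(default=())


def fit_standard_curve(series: DilutionSeries) -> StandardCurve:
    """Ordinary least squares of Ct on log10 relative concentration.

    R-squared is the squared Pearson correlation of the same fit (what
    instrument software reports).  A non-negative slope leaves the efficiency
    undefined (NaN) with a warning.
    """
    x = series.log10_concentration
    y = [ct for _, ct in series.points]
    if len(set(x)) < 2:
        raise CalibrationError(f"{series.primer}: zero variance in concentration")
    fit = stats.linregress(x, y)
    if fit.slope < 0:
        eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    else:
        warnings.warn(
            f"{series.primer}: non-negative slope {fit.slope:.4f}; efficiency undefined",
            stacklevel=2,
        )
        eff = float("nan")
    return StandardCurve(
        primer=series.primer,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=float(eff),
    )


def primer_qc(
    curve: StandardCurve,
    e_lo: float = 0.90,
    e_hi: float = 1.20,
    r2_min: float = 0.99,
) -> QCResult:
    """Accept a primer iff e_lo <= E <= e_hi and R^2 >= r2_min."""
    reasons: list[str] = []
    if math.isnan(curve.efficiency):
        reasons.append("efficiency undefined (non-negative slope)")
    elif curve.efficiency < e_lo:
        reasons.append(f"efficiency {curve.efficiency_pct:.1f}% below {e_lo * 100:.0f}%")
    elif curve.efficiency > e_hi:
        reasons.append(f"efficiency {curve.efficiency_pct:.1f}% above {e_hi * 100:.0f}%")
    if curve.r_squared < r2_min:
        reasons.append(f"R^2 {curve.r_squared:.4f} below {r2_min}")
    return QCResult(primer=curve.primer, passed=not reasons, reasons=tuple(reasons))


def read_dilution_series(path: str | Path, base: float = 5.0, sep: str = ",") -> list[DilutionSeries]:
    """Read a primer,level,ct CSV into one DilutionSeries per primer."""
    df = pd.read_csv(path, sep=sep)
    required = {"primer", "level", "ct"}
    if not required.issubset(df.columns):
        raise CalibrationError(f"{path}: needs columns {sorted(required)}")
    out = []
    for primer, grp in df.groupby("primer", sort=True):
        points = tuple(
            (int(lvl), float(ct)) for lvl, ct in zip(grp["level"], grp["ct"])
        )
        out.append(DilutionSeries(primer=str(primer), points=points, base=base))
    return out


def curves_to_frame(
    curves: Sequence[StandardCurve],
    qc: Sequence[QCResult] | None = None,
) -> pd.DataFrame:
    rows = []
    qc_map = {q.primer: q for q in qc} if qc is not None else {}
    for c in curves:
        q = qc_map.get(c.primer)
        rows.append(
            {
                "primer": c.primer,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "efficiency_pct": c.efficiency_pct,
                "qc_pass": q.passed if q else None,
                "qc_reasons": "; ".join(q.reasons) if q else "",
            }
        )
    return pd.DataFrame(rows).set_index("primer")
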