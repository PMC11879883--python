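"""Adenine-nucleotide quantification via the Wagner log-quadratic curve.

Porous-graphitic-carbon LC-MS/MS response for AMP, ADP and ATP is not
log-linear over a wide standards range; the Wagner calibration models

    ln y = a2·(ln x)² + a1·(ln x) + a0

with y the peak area and x the standard concentration.  A curve is
usable only when the ln-space regression reaches R² > 0.99.  Sample
concentrations are recovered by inverting the quadratic inside the
standards range, and cellular energy state is reported as AMP/ATP and
ADP/ATP ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "R2_GATE",
    "WagnerCurve",
    "CalibrationRangeError",
    "fit_wagner",
    "invert_wagner",
    "nucleotide_ratios",
    "read_standards",
    "quantify_samples",
]

R2_GATE = 0.99
_LINEAR_EPS = 1e-12


class CalibrationRangeError(ValueError):
    """Inversion failed: no usable root inside the standards range."""


@dataclass(frozen=True)
class WagnerCurve:
    a0: float
    a1: float
    a2: float
    r_squared: float
    x_range: tuple[float, float]

    @property
    def usable(self) -> bool:
        return self.r_squared > R2_GATE

    def predict(self, x) -> np.ndarray:
        u = np.log(np.asarray(x, dtype=float))
        return np.exp(self.a2 * u * u + self.a1 * u + self.a0)


def fit_wagner(x, y) -> WagnerCurve:
    """Least-squares fit of ln y on (ln x)², ln x, 1.

    Needs at least three standards with distinct positive concentrations
    and positive areas.  R² is that of the ln-space regression; a curve
    with R² ≤ 0.99 is returned but flagged unusable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("standards require positive concentrations and areas")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 standards with distinct concentrations")
    u = np.log(x)
    v = np.log(y)
    design = np.column_stack([u * u, u, np.ones_like(u)])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    a2, a1, a0 = (float(c) for c in coef)
    resid = v - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return WagnerCurve(
        a0=a0, a1=a1, a2=a2, r_squared=r2,
        x_range=(float(x.min()), float(x.max())),
    )


def invert_wagner(curve: WagnerCurve, y: float) -> float:
    """Concentration whose predicted area equals ``y``.

    Solves a2·u² + a1·u + (a0 − ln y) = 0 for u = ln x and returns
    exp(u) for the unique root inside the calibration range.  Ambiguous
    (two in-range roots) or out-of-range solutions are errors: the curve
    only quantifies within its standards.
    """
    if not curve.usable:
        raise ValueError(
            f"curve unusable (R² = {curve.r_squared:.4f} ≤ {R2_GATE})"
        )
    if y <= 0:
        raise ValueError("area must be positive")
    lo, hi = (math.log(curve.x_range[0]), math.log(curve.x_range[1]))
    c = curve.a0 - math.log(y)
    if abs(curve.a2) < _LINEAR_EPS:
        if curve.a1 == 0:
            raise CalibrationRangeError("degenerate flat calibration curve")
        roots = [-c / curve.a1]
    else:
        disc = curve.a1 * curve.a1 - 4.0 * curve.a2 * c
        if disc < 0:
            raise CalibrationRangeError(
                "negative discriminant: area unreachable by the curve"
            )
        sq = math.sqrt(disc)
        roots = [(-curve.a1 - sq) / (2 * curve.a2), (-curve.a1 + sq) / (2 * curve.a2)]
    tol = 1e-9 * max(abs(lo), abs(hi), 1.0)
    in_range = [u for u in roots if lo - tol <= u <= hi + tol]
    if not in_range:
        raise CalibrationRangeError(
            f"no root inside the calibration range "
            f"[{curve.x_range[0]:.4g}, {curve.x_range[1]:.4g}]"
        )
    if len(in_range) == 2 and abs(in_range[0] - in_range[1]) > tol:
        raise CalibrationRangeError(
            "ambiguous calibration: two concentrations match this area"
        )
    return math.exp(in_range[0])


def nucleotide_ratios(amp: float, adp: float, atp: float) -> tuple[float, float]:
    """(AMP/ATP, ADP/ATP) energy-state ratios."""
    if atp <= 0:
        raise ValueError("ATP concentration must be positive to form ratios")
    if amp < 0 or adp < 0:
        raise ValueError("concentrations must be non-negative")
    return amp / atp, adp / atp


def read_standards(path: str | Path) -> dict[str, WagnerCurve]:
    """Fit one Wagner curve per nucleotide from a standards CSV.

    Schema: ``nucleotide,conc,area``.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("nucleotide", "conc", "area") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: standards table missing columns {missing}")
    return {
        nuc: fit_wagner(grp["conc"].to_numpy(), grp["area"].to_numpy())
        for nuc, grp in df.groupby("nucleotide")
    }


def quantify_samples(
    samples: pd.DataFrame, curves: dict[str, WagnerCurve]
) -> pd.DataFrame:
    """Invert sample areas to concentrations and derive energy ratios.

    ``samples`` has columns ``nucleotide,sample,area``; output has one
    row per sample with AMP, ADP, ATP concentrations plus AMP/ATP and
    ADP/ATP.
    """
    rows = []
    for sample, grp in samples.groupby("sample"):
        conc = {}
        for row in grp.itertuples(index=False):
            if row.nucleotide not in curves:
                raise KeyError(f"no calibration curve for {row.nucleotide!r}")
            conc[row.nucleotide] = invert_wagner(curves[row.nucleotide], row.area)
        amp_atp, adp_atp = nucleotide_ratios(
            conc.get("AMP", 0.0), conc.get("ADP", 0.0), conc.get("ATP", 0.0)
        )
        rows.append(
            {
                "sample": sample,
                "AMP": conc.get("AMP"),
                "ADP": conc.get("ADP"),
                "ATP": conc.get("ATP"),
                "AMP_ATP": amp_atp,
                "ADP_ATP": adp_atp,
            }
        )
    return pd.DataFrame(rows)
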