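"""Flyability (ionization-efficiency) calibration.

Cognate phospho/dephospho peptides ionize with different efficiencies,
so their raw EIC area ratio misstates the phosphorylation occupancy.
The correction factor k is calibrated from two samples of identical
peptide amount: A, with low phosphorylation (phosphatase-treated), and
B, with high phosphorylation (untreated):

    k = |I_PA − I_PB| / |I_pPA − I_pPB|

Dephosphorylating the sample converts phosphopeptide into its cognate,
so the gain in dephospho area per unit loss of phospho area is exactly
the ratio of their per-mole responses.  The raw differences have
opposite signs when A/B form a valid dephosphorylation pair (dephospho
area rises from B to A while phospho area falls); magnitudes are used
for k and the sign direction is verified separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .quant_model import CognatePair, aggregate_charge_areas

__all__ = [
    "CalibrationError",
    "FlyabilityCalibration",
    "average_technical_replicates",
    "compute_flyability",
    "calibrate_from_report",
]

#: Relative tolerance below which the phospho-area change is treated as
#: no change (calibration uninformative).
DENOMINATOR_RTOL = 1e-6


class CalibrationError(ValueError):
    """Calibration pair is uninformative or physically inconsistent."""


@dataclass(frozen=True)
class FlyabilityCalibration:
    site_label: str
    k: float
    #: technical-replicate-averaged (I_P, I_pP) for the low-phos sample A
    inputs_a: tuple[float, float]
    #: technical-replicate-averaged (I_P, I_pP) for the high-phos sample B
    inputs_b: tuple[float, float]
    #: True when the raw differences have the expected opposite signs
    sign_consistent: bool
    #: max over species of the relative spread (sd/mean) across injections
    replicate_spread: float


def average_technical_replicates(
    measurements: pd.DataFrame, pair: CognatePair, sample_id: str
) -> tuple[float, float, float]:
    """Mean charge-aggregated (I_P, I_pP) over a sample's injections.

    Returns ``(I_P, I_pP, spread)`` where spread is the largest relative
    standard deviation (sd/mean, ddof=1) across the technical replicates
    of either species — a quick injection-repeatability diagnostic
    (0.0 when only one injection exists).
    """
    reps = sorted(
        measurements.loc[measurements["sample"] == sample_id, "replicate"].unique()
    )
    if not reps:
        raise CalibrationError(f"no measurements for sample {sample_id!r}")
    per_rep = [
        aggregate_charge_areas(measurements, pair, sample_id, r) for r in reps
    ]
    df = pd.DataFrame(per_rep, columns=["I_P", "I_pP"])
    means = df.mean()
    spread = 0.0
    if len(df) > 1:
        rel = (df.std(ddof=1) / means.where(means > 0)).fillna(0.0)
        spread = float(rel.max())
    return float(means["I_P"]), float(means["I_pP"]), spread


def compute_flyability(
    a: tuple[float, float],
    b: tuple[float, float],
    *,
    site_label: str = "",
    replicate_spread: float = 0.0,
) -> FlyabilityCalibration:
    """Flyability ratio k from averaged (I_P, I_pP) of samples A and B.

    ``a`` is the low-phosphorylation sample, ``b`` the high one.  Raises
    :class:`CalibrationError` when the phospho areas barely differ (the
    pair carries no calibration information) or when the area changes do
    not run in opposite directions (A/B is then not a valid
    dephosphorylation pair).
    """
    i_pa, i_ppa = a
    i_pb, i_ppb = b
    num = i_pa - i_pb
    den = i_ppa - i_ppb
    if abs(den) <= DENOMINATOR_RTOL * max(i_ppa, i_ppb, 1e-300):
        raise CalibrationError(
            f"{site_label}: no phospho-signal change between A and B — "
            "calibration uninformative"
        )
    sign_consistent = num > 0 and den < 0
    if not sign_consistent:
        raise CalibrationError(
            f"{site_label}: A/B samples are not a valid dephosphorylation "
            f"pair (ΔI_P = {num:.4g}, ΔI_pP = {den:.4g}; expected dephospho "
            "area to rise and phospho area to fall from B to A)"
        )
    k = abs(num) / abs(den)
    if not (k > 0) or k != k or k == float("inf"):
        raise CalibrationError(f"{site_label}: non-finite flyability ratio")
    return FlyabilityCalibration(
        site_label=site_label,
        k=k,
        inputs_a=(i_pa, i_ppa),
        inputs_b=(i_pb, i_ppb),
        sign_consistent=sign_consistent,
        replicate_spread=replicate_spread,
    )


def calibrate_from_report(
    measurements: pd.DataFrame,
    pairs: list[CognatePair],
    sample_a: str,
    sample_b: str,
) -> dict[str, FlyabilityCalibration]:
    """Calibrate every cognate pair from a two-sample report.

    Technical injections of each sample are averaged per species before
    forming the ratio.
    """
    out: dict[str, FlyabilityCalibration] = {}
    for pair in pairs:
        i_pa, i_ppa, spread_a = average_technical_replicates(
            measurements, pair, sample_a
        )
        i_pb, i_ppb, spread_b = average_technical_replicates(
            measurements, pair, sample_b
        )
        out[pair.site_label] = compute_flyability(
            (i_pa, i_ppa),
            (i_pb, i_ppb),
            site_label=pair.site_label,
            replicate_spread=max(spread_a, spread_b),
        )
    return out


def calibration_table(
    calibrations: dict[str, FlyabilityCalibration]
) -> pd.DataFrame:
    """Flatten calibrations into a tidy table (one row per site)."""
    return pd.DataFrame(
        [
            {
                "site_label": c.site_label,
                "flyability_k": c.k,
                "I_P_A": c.inputs_a[0],
                "I_pP_A": c.inputs_a[1],
                "I_P_B": c.inputs_b[0],
                "I_pP_B": c.inputs_b[1],
                "replicate_spread": c.replicate_spread,
            }
            for c in calibrations.values()
        ]
    )
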