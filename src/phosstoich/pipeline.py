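"""End-to-end orchestration: report → screen → calibrate → occupancy → stats."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import flyability as fly
from . import quant_model as qm
from . import stoichiometry as st

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    targets_path: str | Path | None  # None -> bundled AMPK panel
    report_path: str | Path
    out_dir: str | Path
    #: separate calibration-pair report; falls back to the main report
    calibration_report_path: str | Path | None = None
    sample_a: str | None = None  # low-phosphorylation calibration sample
    sample_b: str | None = None  # high-phosphorylation calibration sample
    control_sample: str | None = None
    diphospho_threshold: float = 0.10
    joint_isomers: bool = False
    dunnett_method: str = "quadrature"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.diphospho_threshold < 1:
            raise ValueError("di-phospho threshold must be in (0, 1)")
        if (self.sample_a is None) != (self.sample_b is None):
            raise ValueError("calibration needs both sample_a and sample_b")


@dataclass
class PipelineResult:
    stoichiometry: pd.DataFrame
    comparisons: pd.DataFrame | None
    calibration: pd.DataFrame | None
    screens: list[qm.SpeciesScreenReport] = field(default_factory=list)


def _screen_report(
    measurements: pd.DataFrame, threshold: float
) -> tuple[pd.DataFrame, list[qm.SpeciesScreenReport]]:
    """Apply the di-phospho screen per base peptide; drop excluded rows."""
    from .peptide_chemistry import parse_peptide_string

    species = measurements["species"].unique()
    by_base: dict[str, dict[str, float]] = {}
    for sp in species:
        pep = parse_peptide_string(sp.split("#")[0])
        totals = by_base.setdefault(pep.residues, {})
        totals[sp] = float(
            measurements.loc[measurements["species"] == sp, "area"].sum()
        )
    screens: list[qm.SpeciesScreenReport] = []
    drop: set[str] = set()
    for base, areas in by_base.items():
        n_phos = {
            sp: parse_peptide_string(sp.split("#")[0]).n_phospho for sp in areas
        }
        if not any(n == 1 for n in n_phos.values()):
            continue  # nothing to screen without a mono-phospho species
        if not any(n >= 2 for n in n_phos.values()):
            continue
        report = qm.screen_phosphospecies(
            {sp: a for sp, a in areas.items() if n_phos[sp] >= 1},
            threshold=threshold,
        )
        screens.append(report)
        drop.update(sp for sp, _, _ in report.excluded)
    if drop:
        measurements = measurements[~measurements["species"].isin(drop)]
    return measurements, screens


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full occupancy workflow and write the result CSVs.

    Outputs under ``config.out_dir``: ``stoichiometry.csv`` (one row per
    site and sample with mean ± SEM), ``comparisons.csv`` (Dunnett vs
    control, when a control is named), ``calibration.csv`` (when a
    calibration pair is named), and ``run.log``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phosstoich")
    root.addHandler(log_handler)
    try:
        pairs, table_k = qm.read_targets(config.targets_path)
        measurements = qm.read_peak_report(config.report_path)
        measurements, screens = _screen_report(
            measurements, config.diphospho_threshold
        )

        calibration_df = None
        if config.sample_a is not None:
            calib_source = (
                qm.read_peak_report(config.calibration_report_path)
                if config.calibration_report_path is not None
                else measurements
            )
            calibrations = fly.calibrate_from_report(
                calib_source, pairs, config.sample_a, config.sample_b
            )
            k_by_site = {s: c.k for s, c in calibrations.items()}
            calibration_df = fly.calibration_table(calibrations)
            calibration_df.to_csv(out_dir / "calibration.csv", index=False)
        else:
            k_by_site = table_k
            missing = [p.site_label for p in pairs if p.site_label not in k_by_site]
            if missing:
                raise fly.CalibrationError(
                    f"no flyability ratio for sites {missing} and no "
                    "calibration samples configured"
                )

        calib_samples = {config.sample_a, config.sample_b} - {None}
        quant = measurements[~measurements["sample"].isin(calib_samples)]
        paired = qm.pair_cognates(
            quant, pairs, joint_isomers=config.joint_isomers
        )
        results = st.site_stoichiometry_table(paired, k_by_site)
        stoich_df = st.stoichiometry_frame(results)
        stoich_df.to_csv(out_dir / "stoichiometry.csv", index=False)

        comparisons = None
        if config.control_sample is not None:
            rows = []
            for site, grp in paired.groupby("site_label", sort=False):
                groups = {
                    sample: np.array(
                        [
                            st.compute_stoichiometry(r.I_pP, r.I_P, k_by_site[site])
                            for r in sub.itertuples(index=False)
                        ]
                    )
                    for sample, sub in grp.groupby("sample", sort=False)
                }
                if len(groups) < 2 or min(len(v) for v in groups.values()) < 2:
                    logger.warning(
                        "site %s: not enough groups/replicates for comparison",
                        site,
                    )
                    continue
                cmp_df = st.dunnett_vs_control(
                    groups,
                    config.control_sample,
                    method=config.dunnett_method,
                    seed=config.seed,
                )
                cmp_df.insert(0, "site", site)
                rows.append(cmp_df)
            if rows:
                comparisons = pd.concat(rows, ignore_index=True)
                comparisons = comparisons.rename(
                    columns={"mean_diff": "mean_diff_pct"}
                )
                comparisons.to_csv(out_dir / "comparisons.csv", index=False)

        return PipelineResult(
            stoichiometry=stoich_df,
            comparisons=comparisons,
            calibration=calibration_df,
            screens=screens,
        )
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
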