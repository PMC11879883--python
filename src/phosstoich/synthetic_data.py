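"""Synthetic peak-area reports with known ground truth.

No raw MS data underlies the stoichiometry workflow's public record, so
every pipeline stage is validated against simulated vendor-style
peak-area reports whose generating parameters are known exactly.

Each site is modelled as an independent cognate peptide pool of total
amount T with true occupancy θ and flyability f: the noise-free areas
are

    I_P  = T·(1−θ)·charge_fraction        (dephospho species)
    I_pP = (T·θ/f)·charge_fraction        (phospho species)

i.e. the phosphopeptide yields 1/f of the signal per mole relative to
its dephospho cognate, which makes the occupancy equation with k = f
exact by construction.  Measured areas are the noise-free values times
exp(ε) with ε ~ Normal(0, σ) and σ = √ln(1 + CV²), the ln-space
equivalent of a natural-scale coefficient of variation — areas stay
positive and errors scale with signal, as EIC areas do.

Sites that share a dephospho peptide are kept as independent pools by
tagging the shared species with ``#<site>`` (the report dialect's
positional-isomer tag); competition of co-located sites for one peptide
pool is deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .peptide_chemistry import parse_peptide_string
from .quant_model import CognatePair

__all__ = [
    "SiteSpec",
    "SimulationConfig",
    "GroundTruthLedger",
    "simulate_peak_report",
    "simulate_calibration_pair",
    "simulate_timecourse",
    "simulate_standards",
    "table2_like_config",
]

#: Default total peptide amount per cognate pool (arbitrary EIC units,
#: the scale of a well-detected tryptic peptide).
DEFAULT_TOTAL_AMOUNT = 1.0e7


def _cv_to_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class SiteSpec:
    """Ground-truth definition of one phosphosite's cognate pool."""

    site_label: str
    dephos: str  # species id, bracket dialect (+ optional #tag)
    phos: str
    charges: tuple[int, ...]
    flyability: float
    theta: Mapping[str, float]  # sample label -> occupancy in [0, 1]
    total_amount: float = DEFAULT_TOTAL_AMOUNT
    charge_fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.charges:
            raise ValueError(f"{self.site_label}: no charges")
        fracs = self.charge_fractions or tuple(
            1.0 / len(self.charges) for _ in self.charges
        )
        object.__setattr__(self, "charge_fractions", fracs)
        if len(fracs) != len(self.charges):
            raise ValueError(f"{self.site_label}: one fraction per charge required")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"{self.site_label}: charge fractions must sum to 1")
        if not self.flyability > 0:
            raise ValueError(f"{self.site_label}: flyability must be positive")
        if not self.total_amount > 0:
            raise ValueError(f"{self.site_label}: total amount must be positive")
        for sample, th in self.theta.items():
            if not 0.0 <= th <= 1.0:
                raise ValueError(
                    f"{self.site_label}: occupancy {th} for {sample!r} "
                    "outside [0, 1]"
                )

    def to_cognate_pair(self) -> CognatePair:
        return CognatePair(
            site_label=self.site_label,
            dephos=parse_peptide_string(self.dephos.split("#")[0]),
            phos=parse_peptide_string(self.phos.split("#")[0]),
            charges_used=frozenset(self.charges),
            dephos_species_id=self.dephos,
            phos_species_id=self.phos,
        )


@dataclass(frozen=True)
class SimulationConfig:
    sites: tuple[SiteSpec, ...]
    samples: tuple[str, ...]
    noise_cv: float = 0.10
    n_replicates: int = 3  # biological replicates per sample
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("config has no sites")
        if not self.samples:
            raise ValueError("config has no samples")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for site in self.sites:
            missing = [s for s in self.samples if s not in site.theta]
            if missing:
                raise ValueError(
                    f"{site.site_label}: no occupancy for samples {missing}"
                )

    def cognate_pairs(self) -> list[CognatePair]:
        return [s.to_cognate_pair() for s in self.sites]

    def true_flyability(self) -> dict[str, float]:
        return {s.site_label: s.flyability for s in self.sites}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sites = tuple(
            SiteSpec(
                site_label=s["site_label"],
                dephos=s["dephos"],
                phos=s["phos"],
                charges=tuple(s["charges"]),
                flyability=float(s["flyability"]),
                theta={k: float(v) for k, v in s["theta"].items()},
                total_amount=float(s.get("total_amount", DEFAULT_TOTAL_AMOUNT)),
                charge_fractions=tuple(s.get("charge_fractions", ())),
            )
            for s in raw["sites"]
        )
        return cls(
            sites=sites,
            samples=tuple(raw["samples"]),
            noise_cv=float(raw.get("noise_cv", 0.10)),
            n_replicates=int(raw.get("n_replicates", 3)),
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "samples": list(self.samples),
            "noise_cv": self.noise_cv,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "sites": [
                {
                    "site_label": s.site_label,
                    "dephos": s.dephos,
                    "phos": s.phos,
                    "charges": list(s.charges),
                    "charge_fractions": list(s.charge_fractions),
                    "flyability": s.flyability,
                    "total_amount": s.total_amount,
                    "theta": dict(s.theta),
                }
                for s in self.sites
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class GroundTruthLedger:
    """Noise-free areas and true parameters behind a simulated report."""

    clean_areas: pd.DataFrame  # species, charge, sample, replicate, clean_area
    truth: pd.DataFrame  # site_label, sample, theta, flyability

    def clean_area(self, species: str, charge: int, sample: str, replicate: int) -> float:
        df = self.clean_areas
        row = df[
            (df["species"] == species)
            & (df["charge"] == charge)
            & (df["sample"] == sample)
            & (df["replicate"] == replicate)
        ]
        return float(row["area"].iloc[0])


def _clean_rows(
    site: SiteSpec, sample: str, replicate: int, theta: float
) -> list[dict]:
    rows = []
    t = site.total_amount
    for z, frac in zip(site.charges, site.charge_fractions):
        rows.append(
            {
                "species": site.dephos,
                "charge": z,
                "sample": sample,
                "replicate": replicate,
                "area": t * (1.0 - theta) * frac,
            }
        )
        rows.append(
            {
                "species": site.phos,
                "charge": z,
                "sample": sample,
                "replicate": replicate,
                "area": (t * theta / site.flyability) * frac,
            }
        )
    return rows


def _apply_noise(
    clean: pd.DataFrame, cv: float, rng: np.random.Generator
) -> pd.DataFrame:
    noisy = clean.copy()
    if cv > 0:
        sigma = _cv_to_sigma(cv)
        noisy["area"] = noisy["area"].to_numpy() * np.exp(
            rng.normal(0.0, sigma, size=len(noisy))
        )
    return noisy


def simulate_peak_report(
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruthLedger]:
    """Long-format peak report plus its ground-truth ledger.

    Deterministic under ``config.seed`` (pass ``rng`` to chain several
    draws off one stream instead).  Replicates here are biological:
    each has the same expected areas and independent noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    truth: list[dict] = []
    for site in config.sites:
        for sample in config.samples:
            theta = site.theta[sample]
            truth.append(
                {
                    "site_label": site.site_label,
                    "sample": sample,
                    "theta": theta,
                    "flyability": site.flyability,
                }
            )
            for rep in range(1, config.n_replicates + 1):
                rows.extend(_clean_rows(site, sample, rep, theta))
    clean = pd.DataFrame(rows)
    report = _apply_noise(clean, config.noise_cv, rng)
    return report, GroundTruthLedger(clean_areas=clean, truth=pd.DataFrame(truth))


def simulate_calibration_pair(
    config: SimulationConfig,
    site_label: str,
    *,
    theta_a: float = 0.0,
    theta_b: float | None = None,
    n_technical: int = 3,
    sample_a: str = "calib_A",
    sample_b: str = "calib_B",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruthLedger]:
    """Matched low/high-phosphorylation sample pair for one site.

    Sample A emulates the phosphatase-treated aliquot (complete
    dephosphorylation by default, ``theta_a`` sets a residual); sample B
    the untreated aliquot at the site's baseline occupancy (first
    configured sample) unless ``theta_b`` overrides it.  Both carry the
    same total peptide amount and ``n_technical`` sequential injections.
    """
    sites = {s.site_label: s for s in config.sites}
    if site_label not in sites:
        raise KeyError(f"unknown site {site_label!r}")
    site = sites[site_label]
    if theta_b is None:
        theta_b = site.theta[config.samples[0]]
    calib_site = replace(
        site, theta={sample_a: theta_a, sample_b: theta_b}
    )
    calib_config = SimulationConfig(
        sites=(calib_site,),
        samples=(sample_a, sample_b),
        noise_cv=config.noise_cv,
        n_replicates=n_technical,
        seed=config.seed,
    )
    return simulate_peak_report(calib_config, rng=rng)


def simulate_timecourse(
    config: SimulationConfig,
    decay: Mapping[str, tuple[float, float]],
    timepoints_h: tuple[float, ...],
    *,
    sample_fmt: str = "t{:g}h",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruthLedger, SimulationConfig]:
    """Exponential dephosphorylation time course.

    Per site, ``decay[site] = (plateau, rate)`` drives
    θ(t) = plateau + (θ0 − plateau)·exp(−rate·t) from the baseline
    occupancy θ0 (the first configured sample), emulating acute kinase
    inhibition.  Sites missing from ``decay`` stay at baseline.  Returns
    the report, its ledger and the derived per-timepoint config.
    """
    baseline = config.samples[0]
    samples = tuple(sample_fmt.format(t) for t in timepoints_h)
    new_sites = []
    for site in config.sites:
        theta0 = site.theta[baseline]
        plateau, rate = decay.get(site.site_label, (theta0, 0.0))
        if rate < 0:
            raise ValueError(f"{site.site_label}: decay rate must be >= 0")
        if not 0.0 <= plateau <= theta0:
            raise ValueError(
                f"{site.site_label}: plateau {plateau} outside [0, θ0={theta0}]"
            )
        theta_t = {
            s: plateau + (theta0 - plateau) * float(np.exp(-rate * t))
            for s, t in zip(samples, timepoints_h)
        }
        new_sites.append(replace(site, theta=theta_t))
    tc_config = SimulationConfig(
        sites=tuple(new_sites),
        samples=samples,
        noise_cv=config.noise_cv,
        n_replicates=config.n_replicates,
        seed=config.seed,
    )
    report, ledger = simulate_peak_report(tc_config, rng=rng)
    return report, ledger, tc_config


def simulate_standards(
    a0: float,
    a1: float,
    a2: float,
    x_grid,
    *,
    noise_cv: float = 0.0,
    seed: int = 0,
    nucleotide: str | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Calibration standards from a known log-quadratic response.

    y = exp(a2·(ln x)² + a1·ln x + a0) times multiplicative log-normal
    noise at the given CV.
    """
    x = np.asarray(x_grid, dtype=float)
    if np.any(x <= 0):
        raise ValueError("standard concentrations must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = np.log(x)
    y = np.exp(a2 * u * u + a1 * u + a0)
    if noise_cv > 0:
        y = y * np.exp(rng.normal(0.0, _cv_to_sigma(noise_cv), size=len(x)))
    df = pd.DataFrame({"conc": x, "area": y})
    if nucleotide is not None:
        df.insert(0, "nucleotide", nucleotide)
    return df


def table2_like_config(
    *,
    samples: tuple[str, ...] = ("basal",),
    noise_cv: float = 0.10,
    n_replicates: int = 3,
    seed: int = 0,
) -> SimulationConfig:
    """Default 19-site fixture mirroring the published target panel.

    Peptides, charge states and flyabilities are the panel's printed
    targeting parameters; occupancies are evenly spaced over the 4–96%
    span the study reports (shape only — measured per-site values are
    not treated as recoverable truth).  Sites sharing a dephospho
    peptide get ``#site`` species tags so each remains an independent
    pool.
    """
    from .quant_model import read_targets

    pairs, flyability = read_targets()
    thetas = np.linspace(0.04, 0.96, len(pairs))
    seen_dephos: set[str] = set()
    sites = []
    for pair, theta in zip(pairs, thetas):
        dephos_id = pair.dephos.serialize()
        if dephos_id in seen_dephos:
            dephos_id = f"{dephos_id}#{pair.site_label.split('-')[-1]}"
        else:
            seen_dephos.add(dephos_id)
        sites.append(
            SiteSpec(
                site_label=pair.site_label,
                dephos=dephos_id,
                phos=pair.phos.serialize(),
                charges=tuple(sorted(pair.charges_used)),
                flyability=flyability[pair.site_label],
                theta={s: float(theta) for s in samples},
            )
        )
    return SimulationConfig(
        sites=tuple(sites),
        samples=samples,
        noise_cv=noise_cv,
        n_replicates=n_replicates,
        seed=seed,
    )
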