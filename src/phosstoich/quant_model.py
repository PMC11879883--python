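"""Peak-area report ingestion, charge aggregation, species screening and
cognate pairing.

The atomic input is one extracted-ion-chromatogram (EIC) peak area per
(species, charge, sample, replicate), as exported long-format from a
vendor quantification tool.  This module turns those rows into cognate
(dephospho, phospho) area pairs per site, sample and replicate — the
inputs of the occupancy calculation.

Species identifiers are peptide strings in the bracket dialect of
:mod:`phosstoich.peptide_chemistry`, optionally suffixed with ``#tag``
to disambiguate co-eluting positional isomers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .peptide_chemistry import ModifiedPeptide, parse_peptide_string

logger = logging.getLogger(__name__)

__all__ = [
    "REPORT_COLUMNS",
    "PeakReportError",
    "NoSignalError",
    "CognatePair",
    "SpeciesScreenReport",
    "read_peak_report",
    "write_peak_report",
    "read_targets",
    "builtin_targets_path",
    "aggregate_charge_areas",
    "screen_phosphospecies",
    "pair_cognates",
]

#: Required report columns, in header order; ``rt_min`` is optional.
REPORT_COLUMNS = ["species", "charge", "sample", "replicate", "area"]
_KEY = ["species", "charge", "sample", "replicate"]


class PeakReportError(ValueError):
    """Malformed peak-area report (schema, duplicates, negative areas)."""


class NoSignalError(ValueError):
    """No observed peak area at all for a required species."""


@dataclass(frozen=True)
class CognatePair:
    """One phosphopeptide species mapped to its dephosphorylated cognate.

    The phospho member must carry exactly one more phospho modification
    than the dephospho member on the identical residue sequence.
    """

    site_label: str
    dephos: ModifiedPeptide
    phos: ModifiedPeptide
    charges_used: frozenset[int]
    #: explicit report species ids (bracket dialect + optional ``#tag``);
    #: default to the serialized peptides
    dephos_species_id: str | None = None
    phos_species_id: str | None = None

    def __post_init__(self) -> None:
        if self.phos.residues != self.dephos.residues:
            raise ValueError(
                f"{self.site_label}: phospho and dephospho peptides must share "
                "the identical residue sequence"
            )
        if self.phos.n_phospho != self.dephos.n_phospho + 1:
            raise ValueError(
                f"{self.site_label}: phospho peptide must carry exactly one "
                "more phosphate than its cognate"
            )
        if not self.charges_used:
            raise ValueError(f"{self.site_label}: charges_used is empty")
        if any(z < 1 for z in self.charges_used):
            raise ValueError(f"{self.site_label}: charges must be positive")

    @property
    def dephos_species(self) -> str:
        return self.dephos_species_id or self.dephos.serialize()

    @property
    def phos_species(self) -> str:
        return self.phos_species_id or self.phos.serialize()


@dataclass
class SpeciesScreenReport:
    """Outcome of the multi-phosphospecies screening for one base peptide."""

    base_peptide: str
    retained: list[tuple[str, float]] = field(default_factory=list)
    excluded: list[tuple[str, float, str]] = field(default_factory=list)
    needs_review: list[tuple[str, float, str]] = field(default_factory=list)

    @property
    def n_detected(self) -> int:
        return len(self.retained) + len(self.excluded)


def read_peak_report(path: str | Path) -> pd.DataFrame:
    """Read a long-format peak-area report CSV.

    Schema: ``species,charge,sample,replicate,area[,rt_min]``.  Raises
    :class:`PeakReportError` on missing columns, negative areas or
    duplicate (species, charge, sample, replicate) keys.
    """
    df = pd.read_csv(
        path, dtype={"species": str, "sample": str}, float_precision="round_trip"
    )
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise PeakReportError(f"{path}: missing columns {missing}")
    if df.empty:
        return df
    df["charge"] = df["charge"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    df["area"] = df["area"].astype(float)
    if (df["area"] < 0).any():
        bad = df.loc[df["area"] < 0].iloc[0]
        raise PeakReportError(
            f"{path}: negative area for species {bad['species']!r}"
        )
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        bad = df.loc[dup, _KEY].iloc[0].to_dict()
        raise PeakReportError(f"{path}: duplicate measurement key {bad}")
    return df


def write_peak_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report in the canonical CSV schema (round-trip safe)."""
    cols = REPORT_COLUMNS + (["rt_min"] if "rt_min" in df.columns else [])
    df.to_csv(path, columns=cols, index=False)


def builtin_targets_path() -> Path:
    """Path to the bundled AMPK phosphosite target-definition table."""
    return Path(str(resources.files("phosstoich.data") / "ampk_targets.csv"))


def read_targets(
    path: str | Path | None = None,
) -> tuple[list[CognatePair], dict[str, float]]:
    """Read a target-definition table.

    Columns: ``site_label, protein_isoform, dephos_peptide, phos_peptide,
    charges_used`` (``;``-joined integers) and optional ``flyability_k``.
    Returns the cognate pairs and a ``{site_label: k}`` dict for rows
    that declare a flyability.
    """
    if path is None:
        path = builtin_targets_path()
    df = pd.read_csv(path)
    required = ["site_label", "dephos_peptide", "phos_peptide", "charges_used"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PeakReportError(f"{path}: targets table missing columns {missing}")
    pairs: list[CognatePair] = []
    flyability: dict[str, float] = {}
    for row in df.itertuples(index=False):
        charges = frozenset(int(z) for z in str(row.charges_used).split(";"))
        dephos_id, phos_id = row.dephos_peptide, row.phos_peptide
        pairs.append(
            CognatePair(
                site_label=row.site_label,
                dephos=parse_peptide_string(dephos_id.split("#")[0]),
                phos=parse_peptide_string(phos_id.split("#")[0]),
                charges_used=charges,
                dephos_species_id=dephos_id if "#" in dephos_id else None,
                phos_species_id=phos_id if "#" in phos_id else None,
            )
        )
        k = getattr(row, "flyability_k", None)
        if k is not None and pd.notna(k):
            flyability[row.site_label] = float(k)
    return pairs, flyability


def _sum_species_areas(
    df: pd.DataFrame, species: str, charges: frozenset[int], context: str
) -> float:
    """Sum areas over the requested charges; missing charge counts 0."""
    rows = df[df["species"] == species]
    observed = rows[rows["charge"].isin(charges)]
    if observed.empty:
        raise NoSignalError(f"no signal for species {species!r} ({context})")
    seen = set(observed["charge"])
    for z in sorted(charges - seen):
        logger.warning(
            "species %r: charge %d+ not observed (%s); contributing 0",
            species, z, context,
        )
    return float(observed["area"].sum())


def aggregate_charge_areas(
    measurements: pd.DataFrame,
    pair: CognatePair,
    sample_id: str,
    replicate: int,
) -> tuple[float, float]:
    """Charge-aggregated (I_P, I_pP) for one sample and replicate.

    Areas are summed over the pair's declared charge states; an
    unobserved charge contributes 0 with a logged warning, and a species
    with no observed charge at all raises :class:`NoSignalError`.
    """
    sub = measurements[
        (measurements["sample"] == sample_id)
        & (measurements["replicate"] == replicate)
    ]
    ctx = f"site {pair.site_label}, sample {sample_id!r}, replicate {replicate}"
    i_p = _sum_species_areas(sub, pair.dephos_species, pair.charges_used, ctx)
    i_pp = _sum_species_areas(sub, pair.phos_species, pair.charges_used, ctx)
    return i_p, i_pp


def screen_phosphospecies(
    species_areas: dict[str, float],
    *,
    threshold: float = 0.10,
) -> SpeciesScreenReport:
    """Apply the multi-species screening rules for one base peptide.

    ``species_areas`` maps species strings (bracket dialect, optional
    ``#tag``) to their summed areas.  Mono-phospho positional isomers
    are always retained as separately quantifiable species.  A
    di-(or higher-)phospho species below ``threshold`` of the largest
    mono-phospho species is excluded as unquantifiable; at or above the
    threshold it is retained but flagged for review.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    base = None
    mono: dict[str, float] = {}
    multi: dict[str, float] = {}
    for species, area in species_areas.items():
        pep = parse_peptide_string(species.split("#")[0])
        if base is None:
            base = pep.residues
        elif pep.residues != base:
            raise ValueError(
                "screen_phosphospecies expects species of one base peptide; "
                f"got {base} and {pep.residues}"
            )
        n = pep.n_phospho
        if n >= 2:
            multi[species] = area
        elif n == 1:
            mono[species] = area
        # n == 0: the dephospho cognate is not part of the screen
    if not mono:
        raise ValueError(f"no mono-phospho species present for {base}")
    report = SpeciesScreenReport(base_peptide=base or "")
    largest_mono = max(mono.values())
    for species, area in mono.items():
        report.retained.append((species, area))
    for species, area in multi.items():
        if area < threshold * largest_mono:
            reason = (
                f"<{threshold:.0%} of mono-phospho signal "
                f"({area:.3g} vs {largest_mono:.3g})"
            )
            report.excluded.append((species, area, reason))
            logger.info("excluded %r: %s", species, reason)
        else:
            reason = (
                f"di-phospho at ≥{threshold:.0%} of mono-phospho signal — "
                "needs review"
            )
            report.retained.append((species, area))
            report.needs_review.append((species, area, reason))
            logger.warning("retained %r with flag: %s", species, reason)
    return report


def pair_cognates(
    measurements: pd.DataFrame,
    pairs: list[CognatePair],
    *,
    joint_isomers: bool = False,
) -> pd.DataFrame:
    """Assemble charge-aggregated cognate area pairs.

    One output row per (site, sample, replicate) with columns
    ``site_label, sample, replicate, I_P, I_pP``.  Positional isomers
    sharing a dephospho peptide each get their own row reusing the same
    I_P.  With ``joint_isomers=True`` the dephospho denominator of each
    isomer is augmented by the areas of the *other* phospho species of
    the same base peptide, so occupancies of co-located sites sum
    coherently; the default pairwise mode mirrors per-site reporting.
    """
    rows = []
    samples_reps = measurements[["sample", "replicate"]].drop_duplicates()
    for pair in pairs:
        # phospho species of sibling isomers (same dephos peptide)
        siblings = [
            q.phos_species
            for q in pairs
            if q is not pair and q.dephos_species == pair.dephos_species
        ]
        for sample_id, replicate in samples_reps.itertuples(index=False):
            sub = measurements[
                (measurements["sample"] == sample_id)
                & (measurements["replicate"] == replicate)
            ]
            if sub[sub["species"].isin([pair.dephos_species, pair.phos_species])].empty:
                continue
            i_p, i_pp = aggregate_charge_areas(
                measurements, pair, sample_id, replicate
            )
            if i_p == 0 and i_pp == 0:
                raise NoSignalError(
                    f"site {pair.site_label}: I_P = I_pP = 0 in sample "
                    f"{sample_id!r} replicate {replicate}"
                )
            if joint_isomers:
                ctx = f"joint mode, site {pair.site_label}"
                for sp in siblings:
                    i_p += _sum_species_areas(sub, sp, pair.charges_used, ctx)
            rows.append(
                {
                    "site_label": pair.site_label,
                    "sample": sample_id,
                    "replicate": int(replicate),
                    "I_P": i_p,
                    "I_pP": i_pp,
                }
            )
    return pd.DataFrame(
        rows, columns=["site_label", "sample", "replicate", "I_P", "I_pP"]
    )
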