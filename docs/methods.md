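# Methods

## The quantity being estimated

The phosphorylation stoichiometry (occupancy) of a protein site is the
fraction of the protein population carrying a phosphate on that residue.
In a targeted label-free LC-MS experiment it is estimated from the
extracted-ion-chromatogram (EIC) peak areas of a *cognate pair*: the
phosphopeptide (area I_pP) and the identical-sequence peptide without
the phosphate (area I_P), integrated at the charge states listed in the
target table. Because the two species ionize with different
efficiencies, the raw area ratio is corrected by the flyability ratio k
(the dephospho:phospho per-mole response ratio):

    occupancy(%) = 100 · k·I_pP / (k·I_pP + I_P)

The expression is intrinsically bounded in [0, 100]; the implementation
never clips, so an out-of-range value is treated as a bug, not data.

k is calibrated from two aliquots of identical peptide amount — A,
phosphatase-treated (low phosphorylation) and B, untreated (high
phosphorylation):

    k = |I_PA − I_PB| / |I_pPA − I_pPB|

Dephosphorylation converts phosphopeptide into cognate peptide mole for
mole, so the area gained per area lost is exactly the response ratio.
As a signed expression the ratio is negative when A is the
dephosphorylated sample (the numerator rises while the denominator
falls); the implementation uses magnitudes and *separately* verifies
that the two differences run in opposite directions, raising an error —
not a warning — when they do not, since a same-direction change means
the A/B pair is not a valid dephosphorylation pair at all.

## Mass model

Peptides are written in a compact bracket dialect (`S[+80]GTATPQR`,
`C[−1]...`); a bracket modifies the residue immediately before it, and
unicode minus and ASCII hyphen are interchangeable. `[+80]` maps to the
exact phospho monoisotopic delta **79.96633 Da** and `[−1]` to the loss
of one hydrogen atom (**−1.0078250319 Da**, consistent with an
intramolecular disulfide); precursor m/z is `(M + z·1.00727646688)/z`
with standard residue monoisotopic masses (from pyteomics) plus water
(18.0105646863 Da). These constants reproduce the full 19-site target
panel's printed precursor m/z to four decimal places at the dominant
charges; literal deltas (80, −1) or the hydrogen-atom mass in the
charge term do not, which is what fixes the choices.

## Report processing rules

* **Charge aggregation.** Peak areas are *summed* over the declared
  charge states before any ratio is formed. Summation uses all
  acquired signal and is the variance-minimising combination for
  Poisson-like areas; averaging is an alternative convention and the
  choice is isolated in one function. A declared-but-unobserved charge
  contributes zero with a logged warning; a species with no observed
  charge at all is an error naming the species.
* **Multi-species screening.** Mono-phosphorylated positional isomers
  are always retained as separately quantifiable species (they are
  chromatographically resolved). A di-phosphopeptide below 10% of the
  largest mono-phospho species' summed area is excluded as
  unquantifiable; at or above 10% it is retained but flagged
  `needs-review`, a conservative stand-in since no established handling
  convention exists for that case. The threshold is configurable and
  exclusions are monotone in it.
* **Positional isomers.** Sites sharing a tryptic peptide (e.g. two
  phosphosites four residues apart) are each quantified pairwise against
  the shared dephospho peptide. An optional *joint* mode augments each
  isomer's denominator with the sibling phosphospecies' areas so that
  co-located occupancies sum coherently; it is off by default because
  pairwise quantification matches per-site reporting.
* **Replicate order of operations.** The occupancy equation is applied
  per biological replicate and the replicate occupancies are then
  summarised as mean ± SEM (sd with n−1 denominator over √n; undefined
  at n = 1). Averaging areas first and applying the equation once is
  the other defensible order; per-replicate computation is the one that
  yields a replicate-level dispersion for the SEM and the group tests.
  Technical injections, by contrast, are averaged *before* the
  flyability ratio is formed — they measure the same material.

## Statistics

Treatments are compared to a control group per site with one-way ANOVA
plus Dunnett's many-to-one procedure on the pooled within-group
variance. The adjusted p-value is the two-sided tail probability of
the maximum of the correlated t statistics, evaluated by direct
numerical quadrature of the equicorrelated multivariate-t integral
(Gauss–Hermite in the shared normal factor × Gauss–Legendre in the
pooled scale, 96 × 128 nodes, accurate to ~1e-7); a Monte-Carlo
resampling evaluation of the same null is available as a switchable
alternative, and scipy's independent Dunnett implementation is used as
a cross-check in the tests only. With a single treatment group the
procedure reduces exactly to the pooled two-sided t test, which is
asserted. Unadjusted p-values use the same pooled statistic, making
adjusted ≥ raw a structural identity. No adjustment is made *across*
sites — the family is the set of treatments within one site — so with
many null sites a ~5% per-site false-positive rate is expected and is
visible in the worked example (one false call among fourteen null
sites).

## Adenine nucleotides

Nucleotide response is calibrated per analyte with the Wagner
log-quadratic curve, ln y = a2(ln x)² + a1(ln x) + a0, fitted by least
squares in ln-space. R² is computed on the ln-transformed regression —
the space of the fit — and a curve is usable only above the R² > 0.99
gate, applied as a flag rather than a hard failure so diagnostics stay
inspectable. Inversion solves the quadratic for ln x and accepts only
a unique root inside the standards' concentration range: extrapolation
and ambiguous (non-monotone) solutions are errors. Energy state is
reported as AMP/ATP and ADP/ATP. Note that when the curve's ln-space
dynamic range is wide (three decades of concentration), R² is
insensitive to realistic noise; the gate's discriminating behaviour is
exercised on a narrow 1.3-decade, 8-level standards design where 20%
multiplicative noise fails some fits and 5% passes essentially all.

## The synthetic-data generator

No raw MS data is publicly available for the stoichiometry workflow, so
correctness is established on simulated reports with known truth. Each
site is an independent cognate pool of total amount T (default 1e7 EIC
units, the scale of a well-detected peptide) with occupancy θ and
flyability f; noise-free areas are I_P = T(1−θ)·c_z and
I_pP = (Tθ/f)·c_z per charge fraction c_z, the generative convention
under which the occupancy equation with k = f is exact by construction.
Measured areas multiply the noise-free value by exp(ε),
ε ~ N(0, √ln(1+CV²)) — multiplicative log-normal noise, since areas are
positive and errors scale with signal. The default panel mirrors the
published 19-site target table (peptides, charges, flyabilities
0.58–12.22) with occupancies evenly spanning 4–96%.

Study conditions fixed in advance:

* **Calibration-recovery study** (200 pairs): A fully dephosphorylated
  (the calibration protocol's phosphatase step is described as
  complete), B at 90% occupancy — the protocol explicitly selects B for
  *high* phosphorylation — two charge states, three technical
  injections, CV 10%, flyabilities log-uniform over 0.58–12.22.
* **End-to-end recovery study** (200 sites): θ uniform in [5, 95]%,
  flyability log-uniform in [0.5, 12], CV 10%, three biological
  replicates, with k taken from each site's own simulated calibration
  pair (B at the site's baseline θ, as in the real protocol). A site
  whose calibration pair is uninformative contributes an infinite
  deviation rather than being dropped.
* **Null calibration of the statistics**: 10,000 repetitions of four
  groups of three from one normal distribution; the family-wise
  rejection rate must be 0.05 ± 0.01.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: chromatographic peak shape and
integration error, retention-time drift, charge-state-dependent or
intensity-dependent flyability, competition between co-located
phosphosites for one peptide pool (shared dephospho peptides are
simulated as independent pools, tagged `#site`), missingness, and
between-batch effects. The calibration-pair model also implies that k
is poorly determined for sites whose untreated occupancy is low — the
phospho-area difference is then small relative to noise — which is a
property of the experimental design itself, visible in the worked
example as large relative k errors confined to low-occupancy sites
(where they barely move the occupancy estimate, since the sensitivity
of occupancy to k scales with θ(1−θ)).

## Numerical and degenerate-input conventions

* Calibration denominator tolerance: |ΔI_pP| must exceed 1e-6 of the
  larger phospho area, else the pair is uninformative.
* Inversion treats |a2| < 1e-12 as exactly log-linear.
* Both-groups-degenerate t test with equal means returns p = 1.
* Adjusted p is floored at the raw p to keep the structural inequality
  under quadrature round-off at extreme statistics.
* All simulation entry points are deterministic under an integer seed;
  identical config and seed reproduce reports byte for byte.

## Problem sizes

The shipped analyses and tests use 19–200 sites, 3 replicates, 10,000
Monte-Carlo repetitions for the statistics calibration, and 200
simulated calibration pairs; the full suite runs in well under a minute
on one CPU, and each numbered analysis script in seconds.

## Known limitations

Measured per-site stoichiometries, measured flyability ratios and
measured treatment effects from the original experiments cannot be
recomputed here — they require the raw MS data, which has no public
deposition; this package reproduces the targeting layer (precursor m/z)
exactly and validates the estimators on synthetic data of matching
structure. Flyability ratios are platform-specific and should not be
transferred between LC-MS systems. The pipeline starts at vendor
peak-area exports: peak picking, identification and validation are out
of scope.
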