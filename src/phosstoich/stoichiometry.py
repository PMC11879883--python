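"""Occupancy calculation, replicate summaries and treatment comparisons.

The occupancy (phosphorylation stoichiometry) of a site is the
flyability-corrected fraction of molecules carrying the phosphate:

    occupancy(%) = 100 · k·I_pP / (k·I_pP + I_P)

with I_pP and I_P the charge-aggregated phospho/dephospho peak areas
and k the pair's flyability ratio.  The expression is intrinsically
bounded in [0, 100]; values are never clipped, so an out-of-range
result signals a bug upstream.

Occupancy is computed per biological replicate and then summarised as
mean ± SEM; treatments are compared against a control group with
Dunnett's many-to-one procedure on the pooled within-group variance.
The Dunnett adjusted p-value is evaluated here by numerical quadrature
of the equicorrelated multivariate-t tail probability (with a
resampling alternative); both reduce to the pooled two-sample t test
when only one treatment is compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "StoichiometryResult",
    "compute_stoichiometry",
    "summarize_mean_sem",
    "site_stoichiometry_table",
    "dunnett_joint_cdf",
    "dunnett_critical_value",
    "dunnett_vs_control",
    "unpaired_t",
]


@dataclass(frozen=True)
class StoichiometryResult:
    site_label: str
    sample_id: str
    replicate_values: tuple[float, ...]  # percent
    mean: float
    sem: float  # NaN when n == 1 (undefined)
    n: int
    k_used: float


def compute_stoichiometry(i_pp: float, i_p: float, k: float) -> float:
    """Flyability-corrected occupancy in percent."""
    if not k > 0:
        raise ValueError(f"flyability ratio must be positive, got {k}")
    if i_pp < 0 or i_p < 0:
        raise ValueError("peak areas must be non-negative")
    if i_pp + i_p == 0:
        raise ValueError("no signal: both peak areas are zero")
    return 100.0 * k * i_pp / (k * i_pp + i_p)


def summarize_mean_sem(values) -> tuple[float, float, int]:
    """Arithmetic mean and standard error (sd with n−1 denominator / √n).

    With a single value the SEM is undefined and returned as NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    n = int(arr.size)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, n


def site_stoichiometry_table(
    paired: pd.DataFrame,
    flyability: dict[str, float],
) -> list[StoichiometryResult]:
    """Per-site, per-sample occupancy summaries.

    ``paired`` is the output of :func:`phosstoich.quant_model.pair_cognates`
    (columns site_label, sample, replicate, I_P, I_pP); ``flyability``
    maps every site to its k.  Occupancy is computed independently per
    replicate and then summarised.
    """
    results: list[StoichiometryResult] = []
    for (site, sample), grp in paired.groupby(["site_label", "sample"], sort=False):
        if site not in flyability:
            raise KeyError(f"no flyability ratio for site {site!r}")
        k = flyability[site]
        grp = grp.sort_values("replicate")
        vals = tuple(
            compute_stoichiometry(row.I_pP, row.I_P, k)
            for row in grp.itertuples(index=False)
        )
        mean, sem, n = summarize_mean_sem(vals)
        results.append(
            StoichiometryResult(
                site_label=site,
                sample_id=sample,
                replicate_values=vals,
                mean=mean,
                sem=sem,
                n=n,
                k_used=k,
            )
        )
    return results


def stoichiometry_frame(results: list[StoichiometryResult]) -> pd.DataFrame:
    """Tidy CSV-ready frame: site,sample,n,mean_pct,sem_pct,replicate_values."""
    return pd.DataFrame(
        [
            {
                "site": r.site_label,
                "sample": r.sample_id,
                "n": r.n,
                "mean_pct": r.mean,
                "sem_pct": r.sem,
                "replicate_values": ";".join(f"{v:.6g}" for v in r.replicate_values),
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------
#
# With k treatment groups of sizes n_i compared against a control of
# size n_0 using the pooled within-group variance s² on ν degrees of
# freedom, the statistics T_i = (x̄_i − x̄_0)/(s·√(1/n_i + 1/n_0)) are
# jointly multivariate t with correlations ρ_ij = λ_i λ_j where
# λ_i = √(n_i/(n_i + n_0)).  Writing Z_i = λ_i Z0 + √(1−λ_i²) X_i with
# independent standard normals and S² = χ²_ν/ν, the two-sided joint
# probability factorises into a double integral over Z0 and S, which is
# evaluated with Gauss–Hermite × Gauss–Legendre quadrature.

_GH_NODES = 96
_GL_NODES = 128


def _chi_density(s: np.ndarray, df: int) -> np.ndarray:
    # density of S = chi_df / sqrt(df)
    logc = (
        math.log(2.0)
        + 0.5 * df * math.log(df / 2.0)
        - math.lgamma(df / 2.0)
    )
    return np.exp(logc + (df - 1) * np.log(s) - df * s * s / 2.0)


def dunnett_joint_cdf(q: float, lambdas: np.ndarray, df: int) -> float:
    """P(max_i |T_i| ≤ q) for the two-sided Dunnett statistic."""
    if q <= 0:
        return 0.0
    if math.isinf(q):
        return 1.0
    lambdas = np.asarray(lambdas, dtype=float)
    gammas = np.sqrt(1.0 - lambdas**2)
    # Z0 integral: Gauss-Hermite for weight exp(-z^2/2)/sqrt(2*pi)
    z, wz = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    wz = wz / math.sqrt(2.0 * math.pi)
    # S integral over (0, s_hi] capturing all but ~1e-14 of the mass
    s_hi = math.sqrt(stats.chi2.ppf(1.0 - 1e-14, df) / df)
    u, wu = np.polynomial.legendre.leggauss(_GL_NODES)
    s = 0.5 * s_hi * (u + 1.0)
    ws = 0.5 * s_hi * wu * _chi_density(s, df)
    # inner product over comparisons: Phi((q s + lam z)/gam) - Phi((-q s + lam z)/gam)
    qs = q * s[:, None]  # (S, 1)
    lz = lambdas[None, None, :] * z[None, :, None]  # (1, Z, K)
    g = gammas[None, None, :]
    upper = (qs[:, :, None] + lz) / g
    lower = (-qs[:, :, None] + lz) / g
    prod = np.prod(stats.norm.cdf(upper) - stats.norm.cdf(lower), axis=2)
    inner = prod @ wz  # (S,)
    return float(np.clip(inner @ ws, 0.0, 1.0))


def dunnett_critical_value(
    lambdas: np.ndarray, df: int, alpha: float = 0.05
) -> float:
    """Two-sided critical value q with P(max|T_i| > q) = alpha."""
    f = lambda q: dunnett_joint_cdf(q, lambdas, df) - (1.0 - alpha)
    return float(brentq(f, 1e-6, 50.0, xtol=1e-10))


def _dunnett_pvalues_resampling(
    t_obs: np.ndarray,
    ns: np.ndarray,
    n0: int,
    df: int,
    n_resample: int,
    rng: np.random.Generator,
) -> np.ndarray:
    lambdas = np.sqrt(ns / (ns + n0))
    gammas = np.sqrt(1.0 - lambdas**2)
    z0 = rng.standard_normal(n_resample)
    x = rng.standard_normal((n_resample, len(ns)))
    s = np.sqrt(rng.chisquare(df, n_resample) / df)
    tmax = np.max(np.abs(lambdas * z0[:, None] + gammas * x), axis=1) / s
    # add-one estimator keeps p in (0, 1]
    return np.array(
        [(np.sum(tmax >= abs(t)) + 1) / (n_resample + 1) for t in t_obs]
    )


def dunnett_vs_control(
    groups: dict[str, np.ndarray],
    control: str,
    *,
    method: str = "quadrature",
    n_resample: int = 200_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-way ANOVA plus Dunnett many-to-one comparisons vs a control.

    Every group needs at least two replicates.  Returns one row per
    non-control group with the mean difference, the unadjusted
    pooled-variance two-sided p and the Dunnett-adjusted p (which is
    never smaller).  ``method`` selects the adjusted-p evaluation:
    ``"quadrature"`` (numerical multivariate-t probability, default) or
    ``"resampling"`` (Monte-Carlo null of the max-|t| statistic).
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least one treatment group besides the control")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {label!r} has n < 2")
    treatments = [k for k in arrays if k != control]
    x0 = arrays[control]
    n0 = x0.size
    ns = np.array([arrays[t].size for t in treatments])
    # pooled within-group variance over ALL groups (the ANOVA MSE)
    all_arrays = list(arrays.values())
    df = sum(a.size for a in all_arrays) - len(all_arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in all_arrays)
    s2 = ss_within / df
    f_stat, anova_p = stats.f_oneway(*all_arrays)

    mean_diff = np.array([arrays[t].mean() - x0.mean() for t in treatments])
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    if s2 == 0:
        t_obs = np.where(mean_diff == 0, 0.0, np.inf * np.sign(mean_diff))
    else:
        t_obs = mean_diff / se
    raw_p = 2.0 * stats.t.sf(np.abs(t_obs), df)

    lambdas = np.sqrt(ns / (ns + n0))
    if method == "quadrature":
        adj_p = np.array(
            [1.0 - dunnett_joint_cdf(abs(t), lambdas, df) for t in t_obs]
        )
    elif method == "resampling":
        rng = np.random.default_rng(seed)
        adj_p = _dunnett_pvalues_resampling(t_obs, ns, n0, df, n_resample, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    # numerical floor: the joint probability can undercut the marginal
    # one by quadrature error at extreme t; the inequality is structural
    adj_p = np.maximum(adj_p, raw_p)

    return pd.DataFrame(
        {
            "control": control,
            "treatment": treatments,
            "mean_diff": mean_diff,
            "raw_p": raw_p,
            "adj_p": np.clip(adj_p, 0.0, 1.0),
            "anova_F": f_stat,
            "anova_p": anova_p,
        }
    )


def unpaired_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided unpaired (pooled-variance) t test.

    When both groups are degenerate (zero variance) with equal means the
    statistic is taken as 0 with p = 1.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
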