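"""Synthetic GWAS and cohort generator with known causal truth.

Emulates the statistical structure a cis-MR analysis assumes:

* a cis region of SNPs with first-order-autoregressive LD (two haplotypes
  per individual, each a thresholded latent AR(1) Gaussian);
* a log-normal biomarker (ln-CRP-like) with additive per-allele effects on
  the log scale;
* an independent case-control sample whose disease status follows a
  logistic model with a tunable causal effect ``theta`` of the biomarker
  and tunable direct (pleiotropic) variant effects ``gamma``;
* per-variant association scans (least squares for the quantitative trait,
  per-variant logistic regression for the binary one) producing the
  summary-statistics tables two-sample MR consumes;
* a biobank-like individual-level cohort (dosages, biomarker, age, sex,
  10 principal components).

Every generator is a pure function of its configuration and seed.  The
generating parameters are kept in a :class:`SimTruth` for recovery tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grs import PC_COLUMNS, CohortTable
from .instruments import CisRegion, LDMatrix
from .sumstats import SumStatTable, from_arrays

#: Synthetic cis region: the IL6R gene body (chromosome 1) with a 300 kb flank.
SYNTH_REGION = CisRegion(chrom="1", gene_start=154_377_669, gene_end=154_441_926, flank=300_000)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]  # non-palindromic


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic two-sample MR study.

    Defaults describe a positive-control-like study: 26 cis variants whose
    strength (F statistics roughly 40-1600 at the exposure sample size)
    matches a large biomarker GWAS, a unit-SD log-scale biomarker, a causal
    log-odds of 0.661 per ln-unit (an OR of ~0.79 per 30% biomarker
    decrement), no pleiotropy, and a ~5% outcome prevalence.
    """

    m_variants: int = 26
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.3  # adjacent-variant latent AR(1) correlation
    a: tuple[float, ...] | None = None  # per-variant exposure effects (ln-trait units)
    f_range: tuple[float, float] = (40.0, 1600.0)  # used to draw `a` when None
    exposure_sd: float = 1.0
    theta: float = 0.661  # causal log-odds per ln-trait unit
    gamma: tuple[float, ...] | None = None  # direct variant log-odds (pleiotropy)
    prevalence_intercept: float = -3.0
    n_exposure_sample: int = 100_000
    n_outcome_sample: int = 150_000
    n_cohort: int = 100_000
    age_mean: float = 57.1
    age_sd: float = 8.1
    female_fraction: float = 0.542
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        for name in ("n_exposure_sample", "n_outcome_sample", "n_cohort"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for vec in (self.a, self.gamma):
            if vec is not None and len(vec) != self.m_variants:
                raise ValueError("effect vectors must have length m_variants")


@dataclass
class SimTruth:
    """Realized generating parameters, kept for recovery tests."""

    a: np.ndarray
    theta: float
    gamma: np.ndarray
    mafs: np.ndarray
    ld_r2: LDMatrix
    variant_ids: list[str]
    region: CisRegion = SYNTH_REGION
    config: SimConfig | None = None


@dataclass
class TwoSampleStudy:
    exposure: SumStatTable
    outcome: SumStatTable
    truth: SimTruth


def _variant_meta(m: int) -> tuple[list[str], np.ndarray, list[str], list[str]]:
    ids = [f"var{j:04d}" for j in range(m)]
    span = SYNTH_REGION.end - SYNTH_REGION.start
    pos = SYNTH_REGION.start + (np.arange(m) + 1) * span // (m + 1)
    ea = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][0] for j in range(m)]
    oa = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][1] for j in range(m)]
    return ids, pos.astype(int), ea, oa


def _draw_params(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (mafs, a, gamma) deterministically from a dedicated stream."""
    m = config.m_variants
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    if config.a is not None:
        a = np.asarray(config.a, dtype=float)
    else:
        # Per-variant F statistics log-uniform in f_range at the exposure
        # sample size: a_j = sqrt(F_j sigma^2 / (n 2 p q)).
        log_f = rng.uniform(np.log(config.f_range[0]), np.log(config.f_range[1]), size=m)
        f = np.exp(log_f)
        het = 2.0 * mafs * (1.0 - mafs)
        a = np.sqrt(f * config.exposure_sd**2 / (config.n_exposure_sample * het))
    gamma = (
        np.asarray(config.gamma, dtype=float) if config.gamma is not None else np.zeros(m)
    )
    return mafs, a, gamma


def draw_params(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The (mafs, a, gamma) that :func:`make_two_sample_study` and
    :func:`make_cohort` will realize for this config — the same parameter
    stream, exposed so callers can calibrate effects to the drawn MAFs."""
    seq = np.random.SeedSequence(config.seed)
    return _draw_params(config, np.random.default_rng(seq.spawn(3)[0]))


def simulate_genotypes(
    config: SimConfig,
    n: int,
    mafs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, LDMatrix, np.ndarray]:
    """Draw an (n, m) dosage matrix with AR(1)-correlated haplotypes.

    Each of the two haplotypes per individual is a latent standard-normal
    AR(1) process across the variants, thresholded at the per-variant MAF
    quantile; the dosage is the haplotype sum.  Returns the dosages, the
    realized dosage r^2 matrix, and the MAFs used.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if mafs is None:
        mafs, _, _ = _draw_params(config, np.random.default_rng(config.seed))
    m = config.m_variants
    rho = config.ld_rho
    z = np.empty((2 * n, m))
    z[:, 0] = rng.standard_normal(2 * n)
    innov_sd = np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + innov_sd * rng.standard_normal(2 * n)
    thresholds = stats.norm.ppf(mafs)
    haplotypes = (z < thresholds[None, :]).astype(np.int8)
    dosages = haplotypes[0::2] + haplotypes[1::2]
    ld = realized_ld(dosages, [f"var{j:04d}" for j in range(m)])
    return dosages.astype(np.int8), ld, np.asarray(mafs, dtype=float)


def realized_ld(dosages: np.ndarray, variant_ids: list[str]) -> LDMatrix:
    """Squared Pearson correlation between dosage columns."""
    with np.errstate(invalid="ignore"):
        corr = np.atleast_2d(np.corrcoef(dosages.astype(float), rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    r2 = np.clip(corr**2, 0.0, 1.0)
    return LDMatrix(variant_ids=variant_ids, r2=r2)


def simulate_exposure(
    genotypes: np.ndarray,
    config: SimConfig,
    mafs: np.ndarray,
    a: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """ln-biomarker: centered additive genetic effects plus normal noise.

    ``ln_trait_i = sum_j a_j (dos_ij - 2 maf_j) + eps_i``; centering keeps
    the trait median near 1, so proportional decrements stay interpretable.
    The positive-scale trait is ``exp(ln_trait)``.
    """
    centered = genotypes.astype(float) - 2.0 * np.asarray(mafs)[None, :]
    genetic = centered @ np.asarray(a, dtype=float)
    return genetic + rng.normal(0.0, config.exposure_sd, size=genotypes.shape[0])


def simulate_outcome(
    genotypes: np.ndarray,
    ln_trait: np.ndarray,
    config: SimConfig,
    gamma: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary disease labels from a logistic model.

    ``logit P(case_i) = intercept + theta * ln_trait_i + sum_j gamma_j dos_ij``.
    """
    eta = (
        config.prevalence_intercept
        + config.theta * ln_trait
        + genotypes.astype(float) @ np.asarray(gamma, dtype=float)
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.uniform(size=len(p)) < p).astype(np.int8)


def _linear_scan(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.dot(xc, xc))
    if sxx == 0:
        return np.nan, np.nan, np.nan
    beta = float(np.dot(xc, yc) / sxx)
    resid = yc - beta * xc
    sigma2 = float(np.dot(resid, resid)) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    if se == 0:
        return beta, 0.0, np.nan
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return beta, float(se), float(p)


def _logistic_scan(x: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10):
    """Newton-Raphson ML fit of logit(y) ~ 1 + x; returns (beta, se, p, converged).

    Hand-rolled two-parameter fit for speed across many variants; validated
    against a general-purpose logistic regression in the test suite.
    """
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    b = np.zeros(2)
    b[0] = np.log(y.mean() / (1.0 - y.mean())) if 0 < y.mean() < 1 else 0.0
    converged = False
    for _ in range(max_iter):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return np.nan, np.nan, np.nan, False
        b = b + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged or abs(b[1]) > 20:
        return np.nan, np.nan, np.nan, False
    eta = X @ b
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = float(np.sqrt(cov[1, 1]))
    p = float(2.0 * stats.norm.sf(abs(b[1]) / se)) if se > 0 else np.nan
    return float(b[1]), se, p, True


def association_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    trait_type: str = "quantitative",
    trait_label: str = "",
    variant_ids: list[str] | None = None,
) -> SumStatTable:
    """Per-variant association table for a quantitative or binary phenotype.

    Quantitative traits use simple least squares per variant; binary traits
    use per-variant logistic maximum likelihood (log-odds with Wald SE).
    Variants with degenerate fits (monomorphic, separation) are excluded.
    """
    n, m = genotypes.shape
    ids, pos, ea, oa = _variant_meta(m)
    if variant_ids is not None:
        ids = list(variant_ids)
    y = np.asarray(phenotype, dtype=float)
    rows = []
    for j in range(m):
        x = genotypes[:, j].astype(float)
        if trait_type == "quantitative":
            beta, se, p = _linear_scan(x, y)
            ok = np.isfinite(beta) and se > 0
        else:
            beta, se, p, ok = _logistic_scan(x, y.astype(float))
            ok = ok and se > 0
        if not ok:
            continue
        rows.append(
            {
                "variant_id": ids[j],
                "chrom": SYNTH_REGION.chrom,
                "pos": int(pos[j]),
                "effect_allele": ea[j],
                "other_allele": oa[j],
                "eaf": float(x.mean() / 2.0),
                "beta": beta,
                "se": se,
                "pvalue": max(p, 5e-324),
                "n": n,
            }
        )
    df = pd.DataFrame(rows)
    return SumStatTable(df=df, trait_label=trait_label, trait_type=trait_type)


def make_two_sample_study(config: SimConfig) -> TwoSampleStudy:
    """Simulate disjoint exposure and outcome samples sharing one truth.

    The exposure sample is scanned against the ln-biomarker (quantitative);
    the outcome sample against disease status (logistic).  Returns both
    summary tables plus the :class:`SimTruth`.
    """
    seq = np.random.SeedSequence(config.seed)
    rng_params, rng_exp, rng_out = (np.random.default_rng(s) for s in seq.spawn(3))
    mafs, a, gamma = _draw_params(config, rng_params)
    ids, _, _, _ = _variant_meta(config.m_variants)

    geno_x, ld_x, _ = simulate_genotypes(config, config.n_exposure_sample, mafs, rng_exp)
    ln_trait_x = simulate_exposure(geno_x, config, mafs, a, rng_exp)
    exposure = association_scan(
        geno_x, ln_trait_x, "quantitative", trait_label="ln_biomarker", variant_ids=ids
    )

    geno_y, _, _ = simulate_genotypes(config, config.n_outcome_sample, mafs, rng_out)
    ln_trait_y = simulate_exposure(geno_y, config, mafs, a, rng_out)
    cases = simulate_outcome(geno_y, ln_trait_y, config, gamma, rng_out)
    outcome = association_scan(
        geno_y, cases, "binary", trait_label="disease", variant_ids=ids
    )

    truth = SimTruth(
        a=a, theta=config.theta, gamma=gamma, mafs=mafs, ld_r2=ld_x, variant_ids=ids,
        config=config,
    )
    return TwoSampleStudy(exposure=exposure, outcome=outcome, truth=truth)


def make_cohort(config: SimConfig, focal_variant: int | None = 0) -> tuple[CohortTable, SimTruth]:
    """Biobank-like individual-level table with known truth.

    Dosages, biomarker (and its log), age ~ N(57.1, 8.1), sex ~
    Bernoulli(0.542), and 10 standard-normal principal components; when
    ``focal_variant`` is set, its genotype is labeled AA/AC/CC by the count
    of that variant's effect allele (0/1/2).
    """
    seq = np.random.SeedSequence(config.seed)
    rng_params, rng_geno, rng_pheno = (np.random.default_rng(s) for s in seq.spawn(3))
    mafs, a, gamma = _draw_params(config, rng_params)
    ids, _, _, _ = _variant_meta(config.m_variants)
    geno, ld, _ = simulate_genotypes(config, config.n_cohort, mafs, rng_geno)
    ln_trait = simulate_exposure(geno, config, mafs, a, rng_pheno)
    n = config.n_cohort
    df = pd.DataFrame({f"dos_{v}": geno[:, j] for j, v in enumerate(ids)})
    df["trait"] = np.exp(ln_trait)
    df["ln_trait"] = ln_trait
    df["age"] = rng_pheno.normal(config.age_mean, config.age_sd, size=n)
    df["sex"] = (rng_pheno.uniform(size=n) < config.female_fraction).astype(int)
    for col in PC_COLUMNS:
        df[col] = rng_pheno.standard_normal(n)
    if focal_variant is not None:
        labels = np.array(["AA", "AC", "CC"])
        df["genotype_class"] = labels[geno[:, focal_variant]]
    truth = SimTruth(
        a=a, theta=config.theta, gamma=gamma, mafs=mafs, ld_r2=ld, variant_ids=ids,
        config=config,
    )
    return CohortTable(df=df), truth


def marginal_log_odds(
    theta: float,
    residual_sd: float = 1.0,
    prevalence_intercept: float = -3.0,
    gh_order: int = 80,
) -> float:
    """Marginal (GWAS-scale) log-odds implied by a conditional causal effect.

    A logistic outcome model is non-collapsible: a per-variant outcome
    association marginalizes over the biomarker variation not attributable
    to that variant (noise plus the other variants), so summary-level MR
    recovers an attenuated slope rather than the conditional ``theta``.
    For an infinitesimal variant effect the marginal logit slope is

    ``theta * E[p (1 - p)] / (K (1 - K))``

    with ``p = expit(intercept + theta * sd * Z)``, ``Z`` standard normal
    and ``K = E[p]`` the prevalence; the expectation is evaluated by
    Gauss-Hermite quadrature.  Attenuation vanishes in the rare-outcome
    limit and is strongest near 50% prevalence.

    Parameters
    ----------
    theta
        Conditional causal log-odds per ln-trait unit.
    residual_sd
        SD of the ln-trait variation a single variant does not explain
        (noise plus remaining genetic variance).
    prevalence_intercept
        Intercept of the logistic disease model.
    """
    if theta == 0.0:
        return 0.0
    x, w = np.polynomial.hermite_e.hermegauss(gh_order)
    w = w / w.sum()
    p = 1.0 / (1.0 + np.exp(-(prevalence_intercept + theta * residual_sd * x)))
    k = float(w @ p)
    return float(theta * (w @ (p * (1.0 - p))) / (k * (1.0 - k)))


def conditional_log_odds(
    marginal: float,
    residual_sd: float = 1.0,
    prevalence_intercept: float = -3.0,
) -> float:
    """Inverse of :func:`marginal_log_odds`: the conditional causal effect
    to configure so the summary-level analysis targets a given marginal
    value (solved numerically)."""
    if marginal == 0.0:
        return 0.0
    from scipy.optimize import brentq

    sign = math.copysign(1.0, marginal)
    hi = 10.0 * abs(marginal) + 1.0
    return float(
        brentq(
            lambda t: marginal_log_odds(sign * t, residual_sd, prevalence_intercept)
            - marginal,
            1e-12,
            hi,
        )
        * sign
    )


def calibrate_theta_for_marginal(config: SimConfig, marginal: float) -> SimConfig:
    """Return a config whose conditional ``theta`` yields the requested
    marginal (GWAS-scale) log-odds under this config's noise, genetic
    variance and prevalence."""
    mafs, a, _ = draw_params(config)
    v_g = float(np.sum(2.0 * mafs * (1.0 - mafs) * a**2))
    sd = math.sqrt(config.exposure_sd**2 + v_g)
    theta = conditional_log_odds(marginal, sd, config.prevalence_intercept)
    return dataclasses.replace(config, theta=theta)


def effects_for_variance_explained(
    mafs: np.ndarray, r2_target: float, exposure_sd: float = 1.0, rng=None
) -> np.ndarray:
    """Scale equal-shape positive effects so the additive genetic variance
    explains ``r2_target`` of the total trait variance.

    With genetic variance v and residual variance sigma^2, R^2 = v/(v+sigma^2),
    so v = r2 sigma^2 / (1 - r2) split equally across variants.
    """
    if not 0 < r2_target < 1:
        raise ValueError("r2_target must be in (0, 1)")
    mafs = np.asarray(mafs, dtype=float)
    v_total = r2_target * exposure_sd**2 / (1.0 - r2_target)
    het = 2.0 * mafs * (1.0 - mafs)
    per_variant = v_total / len(mafs)
    return np.sqrt(per_variant / het)


def sample_summary_instruments(
    a: np.ndarray,
    se_exp: np.ndarray,
    se_out: np.ndarray,
    theta: float,
    gamma: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a harmonized instrument table directly at the summary level.

    ``beta_exp ~ N(a, se_exp)``, ``beta_out ~ N(theta * a + gamma, se_out)``
    — the sampling model the two-sample estimators assume, useful for
    large-replicate calibration studies where individual-level simulation
    would be wasteful.
    """
    if rng is None:
        raise ValueError("an explicit rng is required")
    a = np.asarray(a, dtype=float)
    se_exp = np.broadcast_to(np.asarray(se_exp, dtype=float), a.shape)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), a.shape)
    g = np.zeros_like(a) if gamma is None else np.asarray(gamma, dtype=float)
    beta_exp = rng.normal(a, se_exp)
    beta_out = rng.normal(theta * a + g, se_out)
    return pd.DataFrame(
        {
            "variant_id": [f"var{j:04d}" for j in range(len(a))],
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "beta_out": beta_out,
            "se_out": se_out,
        }
    )
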