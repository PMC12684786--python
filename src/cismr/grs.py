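"""Genetic-risk-score analyses on individual-level cohort data.

Mirrors a biobank-style workup of a biomarker (CRP-like, strictly positive,
analyzed on the natural-log scale): a weighted allele-dosage score, median
contrasts between the top and bottom percentiles of the score, genotype-class
contrasts for a focal variant (Kruskal-Wallis followed by Dunn's pairwise
z tests), and the proportion of ln-biomarker variance explained by a
predictor via ordinary least squares, optionally adjusted for age, sex and
10 genetic principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

DOSAGE_PREFIX = "dos_"
PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]


@dataclass
class CohortTable:
    """One row per individual: dosages, biomarker, covariates.

    Dosage columns are prefixed ``dos_``; covariates are ``age``, ``sex``
    (0/1) and ``pc1..pc10``; ``trait`` is the biomarker on its original
    (positive) scale with ``ln_trait`` its natural log; ``genotype_class``
    (optional) labels a focal variant's genotype (e.g. AA/AC/CC).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["trait", "ln_trait", "age", "sex"] + PC_COLUMNS
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if not self.variant_ids:
            raise ValueError(f"no dosage columns (prefix {DOSAGE_PREFIX!r}) found")
        if (self.df["trait"] <= 0).any():
            raise ValueError("trait must be strictly positive")
        dos = self.dosages
        if dos.min() < -1e-9 or dos.max() > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def variant_ids(self) -> list[str]:
        return [c[len(DOSAGE_PREFIX):] for c in self.df.columns if c.startswith(DOSAGE_PREFIX)]

    @property
    def dosages(self) -> np.ndarray:
        cols = [DOSAGE_PREFIX + v for v in self.variant_ids]
        return self.df[cols].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    def write(self, path, sep: str = "\t") -> None:
        self.df.to_csv(path, sep=sep, index=False, na_rep="NA")

    @classmethod
    def read(cls, path, sep: str = "\t") -> "CohortTable":
        return cls(df=pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False))


@dataclass(frozen=True)
class ContrastResult:
    """A percent change in median biomarker between groups, with bootstrap CI."""

    group_medians: tuple[float, ...]
    percent_change: float
    ci_low: float
    ci_high: float
    n_boot: int
    test_p: float


@dataclass
class GenotypeContrastResult:
    """Per-class median contrasts vs a reference genotype plus rank tests."""

    classes: list[str]
    medians: dict[str, float]
    counts: dict[str, int]
    contrasts: dict[str, ContrastResult]  # class -> contrast vs reference
    kruskal_h: float
    kruskal_df: int
    kruskal_p: float
    dunn: pd.DataFrame = field(default_factory=pd.DataFrame)


def compute_grs(cohort: CohortTable, weights) -> np.ndarray:
    """Per-individual weighted dosage score ``sum_j dosage_ij * weight_j``.

    ``weights`` may be a sequence aligned with the cohort's dosage columns or
    a mapping variant_id -> weight covering all of them.
    """
    if isinstance(weights, dict):
        missing = [v for v in cohort.variant_ids if v not in weights]
        if missing:
            raise ValueError(f"weights missing for variants: {missing}")
        w = np.array([weights[v] for v in cohort.variant_ids], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (len(cohort.variant_ids),):
        raise ValueError(
            f"weight vector length {w.shape} does not match {len(cohort.variant_ids)} dosage columns"
        )
    return cohort.dosages @ w


def _percent_change(median_top: float, median_bottom: float) -> float:
    return 100.0 * (median_top - median_bottom) / median_bottom


def percentile_contrast(
    scores,
    trait,
    percentile: float = 0.01,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> ContrastResult:
    """Median biomarker in the top vs bottom ``percentile`` tail of the score.

    Tails are defined by type-7 quantile cuts of the score.  The CI for the
    percent change comes from a seeded percentile bootstrap resampling both
    tails; ``test_p`` is a two-sided Mann-Whitney U test between the tails.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    if not 0 < percentile < 0.5:
        raise ValueError("percentile must be in (0, 0.5)")
    scores = np.asarray(scores, dtype=float)
    trait = np.asarray(trait, dtype=float)
    lo_cut = np.quantile(scores, percentile)
    hi_cut = np.quantile(scores, 1.0 - percentile)
    bottom = trait[scores <= lo_cut]
    top = trait[scores >= hi_cut]
    if len(bottom) == 0 or len(top) == 0:
        raise ValueError("empty tail: too few individuals for the requested percentile")
    m_bot, m_top = float(np.median(bottom)), float(np.median(top))
    change = _percent_change(m_top, m_bot)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        b = rng.choice(bottom, size=len(bottom), replace=True)
        t = rng.choice(top, size=len(top), replace=True)
        boots[i] = _percent_change(float(np.median(t)), float(np.median(b)))
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    test_p = float(stats.mannwhitneyu(top, bottom, alternative="two-sided").pvalue)
    return ContrastResult(
        group_medians=(m_bot, m_top),
        percent_change=change,
        ci_low=float(min(ci_low, change)),
        ci_high=float(max(ci_high, change)),
        n_boot=n_boot,
        test_p=test_p,
    )


def dunn_test(groups: list[np.ndarray], labels: list[str], p_adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks with tie correction.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` with
    tie term ``T = sum(t^3 - t) / (12 (N - 1))``; on tie-free data this is the
    classical no-tie formula.  P-values are adjusted with the requested
    method (Holm by default).
    """
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start : start + len(g)])))
        start += len(g)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            denom = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term)
                * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
            )
            z = (mean_ranks[i] - mean_ranks[j]) / denom
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "z": float(z),
                    "pvalue": float(2.0 * stats.norm.sf(abs(z))),
                }
            )
    out = pd.DataFrame(rows)
    out["pvalue_adj"] = multipletests(out["pvalue"], method=p_adjust)[1]
    return out


def genotype_contrast(
    cohort: CohortTable,
    reference: str | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
    p_adjust: str = "holm",
) -> GenotypeContrastResult:
    """Median biomarker by genotype class with bootstrap CIs and rank tests.

    The percent decrease of each class's median vs the reference class
    (first class in sorted order unless given) gets a percentile-bootstrap
    CI; global differences are tested by Kruskal-Wallis and pairwise by
    Dunn's test with multiplicity adjustment.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    if "genotype_class" not in cohort.df.columns:
        raise ValueError("cohort table has no genotype_class column")
    classes = sorted(cohort.df["genotype_class"].dropna().unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 non-empty genotype classes")
    if reference is None:
        reference = classes[0]
    if reference not in classes:
        raise ValueError(f"reference class {reference!r} not present (have {classes})")
    groups = [cohort.df.loc[cohort.df["genotype_class"] == c, "trait"].to_numpy() for c in classes]
    medians = {c: float(np.median(g)) for c, g in zip(classes, groups)}
    counts = {c: int(len(g)) for c, g in zip(classes, groups)}
    h, kw_p = stats.kruskal(*groups)
    dunn = dunn_test(groups, classes, p_adjust=p_adjust)

    ref_values = groups[classes.index(reference)]
    rng = np.random.default_rng(seed)
    contrasts: dict[str, ContrastResult] = {}
    for c, g in zip(classes, groups):
        if c == reference:
            continue
        change = _percent_change(medians[c], medians[reference])
        boots = np.empty(n_boot)
        for i in range(n_boot):
            rb = rng.choice(ref_values, size=len(ref_values), replace=True)
            gb = rng.choice(g, size=len(g), replace=True)
            boots[i] = _percent_change(float(np.median(gb)), float(np.median(rb)))
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        pair = dunn[
            ((dunn["group_a"] == reference) & (dunn["group_b"] == c))
            | ((dunn["group_a"] == c) & (dunn["group_b"] == reference))
        ]
        contrasts[c] = ContrastResult(
            group_medians=(medians[reference], medians[c]),
            percent_change=change,
            ci_low=float(min(ci_low, change)),
            ci_high=float(max(ci_high, change)),
            n_boot=n_boot,
            test_p=float(pair["pvalue_adj"].iloc[0]),
        )
    return GenotypeContrastResult(
        classes=classes,
        medians=medians,
        counts=counts,
        contrasts=contrasts,
        kruskal_h=float(h),
        kruskal_df=len(classes) - 1,
        kruskal_p=float(kw_p),
        dunn=dunn,
    )


@dataclass
class VarianceExplainedResult:
    r2: float  # unadjusted R^2 of the univariable fit
    params: pd.DataFrame  # coefficient table of the (possibly adjusted) fit


def ols_variance_explained(
    cohort: CohortTable, predictor, adjusted: bool = False
) -> VarianceExplainedResult:
    """OLS of ln-biomarker on a predictor; returns univariable R^2.

    With ``adjusted=True`` the reported coefficient table additionally
    conditions on age, sex and the 10 principal components; the R^2 is
    always that of the univariable fit (the fraction of biomarker variance
    the predictor alone explains).
    """
    y = cohort.df["ln_trait"].to_numpy(dtype=float)
    x = np.asarray(predictor, dtype=float)
    if x.shape != y.shape:
        raise ValueError("predictor length must match cohort size")
    uni = sm.OLS(y, sm.add_constant(x)).fit()
    if adjusted:
        covars = cohort.df[["age", "sex"] + PC_COLUMNS].to_numpy(dtype=float)
        X = sm.add_constant(np.column_stack([x, covars]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        fit = sm.OLS(y, X).fit()
        names = ["const", "predictor", "age", "sex"] + PC_COLUMNS
    else:
        fit = uni
        names = ["const", "predictor"]
    params = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "pvalue": fit.pvalues}, index=names
    )
    return VarianceExplainedResult(r2=float(uni.rsquared), params=params)
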