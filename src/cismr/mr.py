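"""Two-sample Mendelian randomization estimators and diagnostics.

All estimators consume a harmonized instrument table (columns ``beta_exp``,
``se_exp``, ``beta_out``, ``se_out``, one row per variant, outcome effects
already expressed on the exposure's effect allele) and return
:class:`MREstimate` objects on the per-exposure-unit scale (log-odds per
ln-unit of the biomarker for binary outcomes).

Per-variant Wald ratios ``b_Y / b_X`` are combined by:

* ``ivw_fixed`` — fixed-effect inverse-variance weighting with first-order
  weights ``b_X^2 / se_Y^2`` (exposure-side error ignored in the weights);
  algebraically a weighted least-squares fit of ``b_Y`` on ``b_X`` through
  the origin.
* ``mr_egger`` — the same regression with a free intercept; a nonzero
  intercept estimates directional (unbalanced) pleiotropy.
* ``weighted_median`` — consistent when at least half the weight comes from
  valid instruments.
* ``weighted_mode`` — kernel-density mode of the ratio estimates, consistent
  when the largest cluster of instruments is valid.

Cochran's Q measures heterogeneity of the per-variant ratios around the IVW
estimate; leave-one-out re-estimates IVW dropping each variant in turn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class MREstimate:
    """A method-labeled causal-effect estimate with normal-theory CI and p."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))


@dataclass(frozen=True)
class QResult:
    """Cochran Q heterogeneity statistic with chi-square upper-tail p."""

    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def _pvalue(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def make_estimate(method: str, beta: float, se: float, n_variants: int) -> MREstimate:
    beta = float(beta)
    se = float(se)
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_pvalue(beta, se),
        n_variants=n_variants,
    )


def _unpack(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(instruments, pd.DataFrame):
        df = instruments
        bx = df["beta_exp"].to_numpy(dtype=float)
        sx = df["se_exp"].to_numpy(dtype=float)
        by = df["beta_out"].to_numpy(dtype=float)
        sy = df["se_out"].to_numpy(dtype=float)
    else:  # sequence of HarmonizedInstrument-like objects
        items = list(instruments)
        bx = np.array([h.beta_exp for h in items], dtype=float)
        sx = np.array([h.se_exp for h in items], dtype=float)
        by = np.array([h.beta_out for h in items], dtype=float)
        sy = np.array([h.se_out for h in items], dtype=float)
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("all standard errors must be > 0")
    return bx, sx, by, sy


def _ratios_weights(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if np.any(bx == 0):
        raise ValueError("beta_exp must be nonzero for ratio-based estimators")
    return by / bx, bx**2 / sy**2


def wald_ratio(h) -> MREstimate:
    """Single-instrument causal estimate ``b_Y / b_X`` with first-order SE."""
    if isinstance(h, pd.DataFrame):
        if len(h) != 1:
            raise ValueError("wald_ratio expects exactly one instrument")
        h = next(h.itertuples(index=False))
    if h.beta_exp == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    beta = h.beta_out / h.beta_exp
    se = h.se_out / abs(h.beta_exp)
    return make_estimate("wald_ratio", beta, se, 1)


def ivw_fixed(instruments) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate over >= 2 instruments."""
    bx, _, by, sy = _unpack(instruments)
    if len(bx) < 2:
        raise ValueError("ivw_fixed needs >= 2 instruments; use wald_ratio for one")
    ratios, w = _ratios_weights(bx, by, sy)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return make_estimate("ivw_fixed", beta, se, len(bx))


def cochran_q(instruments, ivw: MREstimate) -> QResult:
    """Heterogeneity of per-variant ratios around the IVW estimate."""
    bx, _, by, sy = _unpack(instruments)
    if len(bx) != ivw.n_variants:
        raise ValueError(
            f"instrument count {len(bx)} does not match ivw.n_variants {ivw.n_variants}"
        )
    if len(bx) < 2:
        raise ValueError("cochran_q needs >= 2 instruments")
    ratios, w = _ratios_weights(bx, by, sy)
    q = float(np.sum(w * (ratios - ivw.beta) ** 2))
    df = len(bx) - 1
    return QResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def mr_egger(instruments) -> EggerResult:
    """Egger regression: WLS of b_Y on b_X with a free intercept.

    Variants are oriented so b_X >= 0 first (the estimator is not invariant
    to allele flips; this is the conventional resolution).  Standard errors
    come from the weighted regression with the residual dispersion floored
    at 1, i.e. multiplicative random effects that never deflate below the
    fixed-effect SE.
    """
    bx, _, by, sy = _unpack(instruments)
    if len(bx) < 3:
        raise ValueError("mr_egger needs >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    X = sm.add_constant(bx)
    res = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    dispersion = max(float(res.scale), 1.0)
    cov = np.asarray(res.normalized_cov_params) * dispersion
    slope_se = float(np.sqrt(cov[1, 1]))
    int_se = float(np.sqrt(cov[0, 0]))
    slope = make_estimate("egger_slope", float(res.params[1]), slope_se, len(bx))
    intercept = float(res.params[0])
    return EggerResult(
        slope=slope,
        intercept=intercept,
        intercept_se=int_se,
        intercept_p=_pvalue(intercept, int_se),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _parametric_boot(bx, sx, by, sy, n_boot, rng):
    """Draw (b_X*, b_Y*) from the instruments' normal errors; shape (n_boot, n)."""
    bx_star = rng.normal(bx, sx, size=(n_boot, len(bx)))
    by_star = rng.normal(by, sy, size=(n_boot, len(by)))
    return bx_star, by_star


def weighted_median(instruments, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Ratios are sorted and the estimate interpolates the standardized
    cumulative weights at 0.5; valid when >= 50% of the weight comes from
    valid instruments.  The SE is the standard deviation of ``n_boot``
    re-estimates with (b_X, b_Y) resampled from their reported errors.
    """
    bx, sx, by, sy = _unpack(instruments)
    if len(bx) < 3:
        raise ValueError("weighted_median needs >= 3 instruments")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap SEs", stacklevel=2)
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    ratios, w = _ratios_weights(bx, by, sy)
    est = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    bx_s, by_s = _parametric_boot(bx, sx, by, sy, n_boot, rng)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx_s[i]
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        boots[i] = _weighted_median(by_s[i] / bxs, bxs**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return make_estimate("weighted_median", est, se, len(bx))


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.percentile(ratios, 75) - np.percentile(ratios, 25))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return phi * 0.9 * spread * len(ratios) ** (-1 / 5)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, h: float, grid_size: int) -> float:
    sd = float(np.std(ratios, ddof=1))
    center = float(np.mean(ratios))
    if sd == 0 or h == 0:
        return float(ratios[0])
    grid = np.linspace(center - 4 * sd, center + 4 * sd, grid_size)
    z = (grid[:, None] - ratios[None, :]) / h
    density = (np.exp(-0.5 * z**2) * weights[None, :]).sum(axis=1)
    return float(grid[np.argmax(density)])


def weighted_mode(
    instruments,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    grid_size: int = 512,
) -> MREstimate:
    """Mode-based estimator: argmax of a weighted normal-kernel density.

    Bandwidth ``phi * 0.9 * min(sd, IQR/1.34) * n^(-1/5)`` over the ratio
    estimates; the density is maximized on a ``grid_size``-point grid
    spanning mean +/- 4 sd.  SE by seeded parametric bootstrap.  If all
    ratios coincide the common ratio is returned directly.
    """
    bx, sx, by, sy = _unpack(instruments)
    if len(bx) < 3:
        raise ValueError("weighted_mode needs >= 3 instruments")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    ratios, w = _ratios_weights(bx, by, sy)
    h = _mode_bandwidth(ratios, phi)
    est = _kde_mode(ratios, w, h, grid_size)
    rng = np.random.default_rng(seed)
    bx_s, by_s = _parametric_boot(bx, sx, by, sy, n_boot, rng)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx_s[i]
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        r = by_s[i] / bxs
        boots[i] = _kde_mode(r, bxs**2 / sy**2, _mode_bandwidth(r, phi), grid_size)
    se = float(np.std(boots, ddof=1))
    return make_estimate("weighted_mode", est, se, len(bx))


def leave_one_out(instruments) -> pd.DataFrame:
    """IVW re-estimated dropping each variant in turn (sensitivity analysis).

    Returns a tidy frame with one row per omitted variant.
    """
    if not isinstance(instruments, pd.DataFrame):
        instruments = pd.DataFrame(
            [
                {
                    "variant_id": getattr(h, "variant_id", str(i)),
                    "beta_exp": h.beta_exp,
                    "se_exp": h.se_exp,
                    "beta_out": h.beta_out,
                    "se_out": h.se_out,
                }
                for i, h in enumerate(instruments)
            ]
        )
    if len(instruments) < 3:
        raise ValueError("leave_one_out needs >= 3 instruments")
    rows = []
    for idx in instruments.index:
        sub = instruments.drop(index=idx)
        est = ivw_fixed(sub)
        rows.append(
            {
                "omitted_variant": instruments.loc[idx, "variant_id"]
                if "variant_id" in instruments.columns
                else str(idx),
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "n_variants": est.n_variants,
            }
        )
    return pd.DataFrame(rows)


def rescale_estimate(est: MREstimate, scale: float) -> MREstimate:
    """Re-express an estimate per ``scale`` exposure units.

    With ``scale = ln(1 - d/100)`` this converts a per-ln-unit log-odds into
    the log-odds per d% biomarker decrement; the z statistic, and hence the
    p-value, is unchanged.
    """
    if scale == 0:
        raise ValueError("scale must be nonzero")
    return make_estimate(est.method, est.beta * scale, est.se * abs(scale), est.n_variants)
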