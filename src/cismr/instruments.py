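"""Genetic-instrument construction for drug-target MR.

Instruments are cis-variants: associations inside a window around the gene
encoding the drug target (here, IL6R for IL-6 signaling, proxied through
circulating CRP), genome-wide significant, and mutually near-independent
after greedy LD clumping at an r-squared threshold.  The module also carries
the instrument-strength diagnostics (per-variant F statistics, cumulative
variance explained) and the decrement-scaling constant that converts
per-ln-unit effects into effects per stated proportional biomarker
reduction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SumStatTable

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 300_000
DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.1


@dataclass(frozen=True)
class CisRegion:
    """A gene body plus symmetric flank, on one chromosome (1-based, inclusive)."""

    chrom: str
    gene_start: int
    gene_end: int
    flank: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError("gene_start must be <= gene_end")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def start(self) -> int:
        return self.gene_start - self.flank

    @property
    def end(self) -> int:
        return self.gene_end + self.flank

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


@dataclass
class LDMatrix:
    """Squared-correlation (r^2) matrix over an ordered set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.variant_ids)
        if self.r2.shape != (m, m):
            raise ValueError(f"r2 shape {self.r2.shape} does not match {m} variant ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-8:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, vid: str) -> bool:
        return vid in self._index

    def write(self, path, sep: str = "\t") -> None:
        pd.DataFrame(self.r2, columns=self.variant_ids).to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "LDMatrix":
        df = pd.read_csv(path, sep=sep)
        return cls(variant_ids=list(df.columns), r2=df.to_numpy(dtype=float))


@dataclass
class InstrumentSet:
    """A clumped, significant instrument with strength diagnostics."""

    table: SumStatTable
    f_stats: pd.Series
    r2_explained: float
    region: CisRegion | None = None
    notes: dict = field(default_factory=dict)


def select_cis_variants(
    table: SumStatTable, region: CisRegion, p_threshold: float = DEFAULT_P_THRESHOLD
) -> SumStatTable:
    """Keep variants inside the cis window (boundaries inclusive) with p below threshold."""
    df = table.df
    if not (df["chrom"].astype(str) == region.chrom).any():
        logger.warning(
            "select_cis_variants: chromosome %r absent from table; empty result", region.chrom
        )
    mask = (
        (df["chrom"].astype(str) == region.chrom)
        & (df["pos"] >= region.start)
        & (df["pos"] <= region.end)
        & (df["pvalue"] < p_threshold)
    )
    return SumStatTable(
        df=df.loc[mask].reset_index(drop=True),
        trait_label=table.trait_label,
        trait_type=table.trait_type,
    )


def ld_clump(table: SumStatTable, ld: LDMatrix, r2_threshold: float = DEFAULT_CLUMP_R2) -> SumStatTable:
    """Greedy LD clumping.

    Repeatedly take the smallest-p unassigned variant as an index and discard
    unassigned variants correlated with it at r^2 >= threshold.  Ties on p are
    broken by variant id, so output is independent of input row order.
    """
    df = table.df
    missing = [v for v in df["variant_id"] if v not in ld]
    if missing:
        raise KeyError(f"variants absent from LD matrix: {missing}")
    order = df.sort_values(["pvalue", "variant_id"], kind="mergesort")
    unassigned = list(order["variant_id"])
    kept: list[str] = []
    while unassigned:
        index_variant = unassigned.pop(0)
        kept.append(index_variant)
        unassigned = [v for v in unassigned if ld.lookup(index_variant, v) < r2_threshold]
    out = df.set_index("variant_id").loc[kept].reset_index()
    return SumStatTable(df=out, trait_label=table.trait_label, trait_type=table.trait_type)


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic ``(beta/se)^2`` for a single variant."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def variance_explained(table: SumStatTable, trait_variance: float = 1.0) -> float:
    """Cumulative trait variance explained under an additive model.

    ``sum_j 2 * eaf_j * (1 - eaf_j) * beta_j^2 / trait_variance``; variants
    are treated as independent, which is an approximation when residual
    LD up to the clumping threshold remains.
    """
    if trait_variance <= 0:
        raise ValueError("trait_variance must be > 0")
    df = table.df
    missing = df.loc[df["eaf"].isna(), "variant_id"].tolist()
    if missing:
        raise ValueError(f"eaf missing for variants: {missing}")
    p = df["eaf"].to_numpy(dtype=float)
    b = df["beta"].to_numpy(dtype=float)
    return float(np.sum(2.0 * p * (1.0 - p) * b**2) / trait_variance)


def build_instrument_set(
    table: SumStatTable,
    region: CisRegion,
    ld: LDMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    clump_r2: float = DEFAULT_CLUMP_R2,
    trait_variance: float = 1.0,
) -> InstrumentSet:
    """Cis filter + significance threshold + LD clump, with diagnostics."""
    cis = select_cis_variants(table, region, p_threshold)
    clumped = ld_clump(cis, ld, clump_r2) if len(cis) else cis
    f = pd.Series(
        [(b / s) ** 2 for b, s in zip(clumped.df["beta"], clumped.df["se"])],
        index=clumped.df["variant_id"],
        name="f_stat",
    )
    r2 = variance_explained(clumped, trait_variance) if len(clumped) else 0.0
    return InstrumentSet(table=clumped, f_stats=f, r2_explained=r2, region=region)


def decrement_scale(percent_decrement: float) -> float:
    """Log-scale change for a stated proportional biomarker reduction.

    A d% reduction on the original scale is ``ln(1 - d/100)`` on the natural
    log scale, e.g. 30 -> ln(0.70) ~ -0.3567; used to re-express per-ln-unit
    causal effects as effects per 30% (or 18%) biomarker decrement.
    """
    if not 0 < percent_decrement < 100:
        raise ValueError("percent_decrement must be in (0, 100)")
    return math.log(1.0 - percent_decrement / 100.0)
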