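"""GWAS summary-statistics I/O and allele harmonization.

A summary-statistics table holds one row per single-nucleotide variant with
its association to a single trait: effect/other allele, effect-allele
frequency, per-allele effect (``beta``), standard error, p-value and sample
size.  Two-sample Mendelian randomization consumes a pair of such tables
(exposure and outcome) after *harmonization* — expressing both effects on
the same effect allele, flipping signs where the allele labels are swapped
and discarding strand-ambiguous (palindromic) variants whose orientation
cannot be resolved from allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: Default header mapping, matching GWAS-SSF-style column names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "rsid",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "n": "n",
}

#: Values parsed as missing on read and written as "NA".
MISSING_SENTINELS = ["NA", "", "."]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ColumnMappingError(KeyError):
    """A mapped column is absent from the input header (configuration error)."""


class EmptyTableError(ValueError):
    """No records survived parsing and invariant filtering."""


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G variant allele pairs (strand-ambiguous)."""
    return _COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class SumStatRecord:
    """One variant's association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int | None


@dataclass
class SumStatTable:
    """Ordered collection of per-variant associations for one trait.

    Backed by a :class:`pandas.DataFrame` with the canonical columns
    (``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
    pvalue, n``); ``variant_id`` is unique.
    """

    df: pd.DataFrame
    trait_label: str = ""
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"table missing canonical columns: {missing}")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant ids: {sorted(set(dups))}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Iterator[SumStatRecord]:
        for row in self.df.itertuples(index=False):
            yield SumStatRecord(
                variant_id=row.variant_id,
                chrom=row.chrom,
                pos=int(row.pos),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=None if pd.isna(row.n) else int(row.n),
            )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects for one variant on a shared effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float | None
    action: str  # match | flip


@dataclass
class HarmonizationResult:
    """Kept instruments plus an exclusion audit trail."""

    instruments: pd.DataFrame  # variant_id, beta_exp, se_exp, beta_out, se_out, eaf, action
    excluded: pd.DataFrame  # variant_id, reason
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.instruments)


def _normalize_and_filter(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Uppercase alleles, coerce numerics and drop rows violating record invariants."""
    drops: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> pd.Series:
        n = int(mask.sum())
        if n:
            drops[reason] = drops.get(reason, 0) + n
        return ~mask

    df = df.copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")

    keep = pd.Series(True, index=df.index)
    snp = df["effect_allele"].isin(_VALID_ALLELES) & df["other_allele"].isin(_VALID_ALLELES)
    keep &= drop(~snp, "non_snp_allele")
    keep &= drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    keep &= drop(df["pos"].isna() | (df["pos"] <= 0), "bad_position")
    keep &= drop(df["beta"].isna() | ~np.isfinite(df["beta"]), "bad_beta")
    keep &= drop(df["se"].isna() | (df["se"] <= 0), "bad_se")
    keep &= drop(df["pvalue"].isna() | (df["pvalue"] <= 0) | (df["pvalue"] > 1), "bad_pvalue")
    keep &= drop(df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1)), "bad_eaf")
    keep &= drop(df["n"].notna() & (df["n"] <= 0), "bad_n")

    # p-value must agree with |beta/se| under a normal approximation within
    # 2-fold (guards against mismatched effect/se columns); tiny p-values that
    # underflow double precision are accepted as consistent.
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(df["beta"] / df["se"])
        p_norm = 2.0 * stats.norm.sf(z)
        both_tiny = (p_norm < 1e-300) & (df["pvalue"] < 1e-250)
        ratio = df["pvalue"] / np.where(p_norm > 0, p_norm, np.nan)
        inconsistent = keep & ~both_tiny & ((ratio < 0.5) | (ratio > 2.0) | ratio.isna())
    keep &= drop(inconsistent, "pvalue_inconsistent")

    out = df.loc[keep].copy()
    out["pos"] = out["pos"].astype("int64")
    return out.reset_index(drop=True), drops


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_label: str = "",
    sep: str = "\t",
) -> SumStatTable:
    """Read a delimited summary-statistics file into a :class:`SumStatTable`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping canonical field name -> input column name.  Defaults to
        GWAS-SSF-style headers (:data:`DEFAULT_COLUMN_MAP`); entries for
        ``eaf`` and ``n`` may be omitted, in which case the fields are missing.
    trait_type
        ``quantitative`` or ``binary``.
    sep
        Field delimiter (tab by default).

    Rows violating record invariants (indels/multi-allelic alleles, se <= 0,
    p outside (0, 1], p inconsistent with |beta/se| beyond 2-fold, ...) are
    dropped and counted in the log.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map is not None:
        cmap.update(column_map)
    raw = pd.read_csv(
        path,
        sep=sep,
        na_values=MISSING_SENTINELS,
        keep_default_na=False,
        dtype={cmap.get("chrom", "chromosome"): str},
    )
    optional = {"eaf", "n"}
    missing_cols = [
        col for key, col in cmap.items() if col not in raw.columns and key not in optional
    ]
    if missing_cols:
        raise ColumnMappingError(
            f"mapped columns absent from {path}: {missing_cols}; header is {list(raw.columns)}"
        )
    data = {}
    for key in CANONICAL_COLUMNS:
        col = cmap.get(key)
        if col is not None and col in raw.columns:
            data[key] = raw[col]
        else:
            data[key] = np.nan
    df = pd.DataFrame(data)
    df, drops = _normalize_and_filter(df)
    if drops:
        logger.info("read_sumstats(%s): dropped rows by reason: %s", path, drops)
    if df.empty:
        raise EmptyTableError(f"no valid records in {path} after filtering ({drops})")
    if df["variant_id"].duplicated().any():
        n_dup = int(df["variant_id"].duplicated().sum())
        logger.info("read_sumstats(%s): dropped %d duplicate variant ids", path, n_dup)
        df = df.drop_duplicates("variant_id", keep="first").reset_index(drop=True)
    return SumStatTable(df=df, trait_label=trait_label, trait_type=trait_type)


def write_sumstats(table: SumStatTable, path, sep: str = "\t") -> None:
    """Write a table in the canonical dialect; missing numerics become ``NA``.

    Floats are written with shortest round-trip repr, so
    ``read(write(t))`` reproduces all numeric fields bit-identically.
    """
    if len(table) == 0:
        logger.warning("write_sumstats(%s): writing empty table (header only)", path)
    out = table.df[CANONICAL_COLUMNS].copy()
    rename = {k: v for k, v in DEFAULT_COLUMN_MAP.items()}
    out = out.rename(columns=rename)
    out.to_csv(path, sep=sep, index=False, na_rep="NA")


def from_arrays(
    variant_id,
    chrom,
    pos,
    effect_allele,
    other_allele,
    eaf,
    beta,
    se,
    pvalue,
    n,
    trait_label: str = "",
    trait_type: str = "quantitative",
) -> SumStatTable:
    """Assemble a table from aligned arrays (used by the simulators)."""
    df = pd.DataFrame(
        {
            "variant_id": variant_id,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": pvalue,
            "n": n,
        }
    )
    return SumStatTable(df=df, trait_label=trait_label, trait_type=trait_type)


def harmonize(
    exposure: SumStatTable,
    outcome: SumStatTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizationResult:
    """Express outcome effects on the exposure's effect allele.

    For each variant shared between the tables:

    * same allele labels (or their strand complement) -> kept, ``action=match``;
    * swapped labels -> outcome beta negated and frequency complemented,
      ``action=flip``;
    * palindromic (A/T or C/G): orientation is decided by allele frequency;
      if the minor-allele frequency is within ``palindrome_eaf_window`` of 0.5
      in either study (or a frequency is missing) the variant is dropped,
      otherwise effects are aligned so both frequencies sit on the same side
      of 0.5;
    * irreconcilable allele sets -> excluded with reason ``allele_mismatch``.

    Variants absent from the outcome are excluded with reason
    ``missing_in_outcome``.  Exclusions are counted, never fatal.
    """
    exp = exposure.df.set_index("variant_id")
    out = outcome.df.set_index("variant_id")

    kept_rows: list[dict] = []
    excluded: list[tuple[str, str]] = []

    for vid, erow in exp.iterrows():
        if vid not in out.index:
            excluded.append((vid, "missing_in_outcome"))
            continue
        orow = out.loc[vid]
        ea_x, oa_x = erow["effect_allele"], erow["other_allele"]
        ea_y, oa_y = orow["effect_allele"], orow["other_allele"]
        beta_y = float(orow["beta"])
        eaf_y = orow["eaf"]

        if is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} not in ({ea_x, oa_x},):
                excluded.append((vid, "allele_mismatch"))
                continue
            eaf_x = erow["eaf"]
            if pd.isna(eaf_x) or pd.isna(eaf_y):
                excluded.append((vid, "drop_palindromic"))
                continue
            maf_x = min(eaf_x, 1.0 - eaf_x)
            maf_y = min(eaf_y, 1.0 - eaf_y)
            near_half = 0.5 - palindrome_eaf_window
            if maf_x > near_half or maf_y > near_half:
                excluded.append((vid, "drop_palindromic"))
                continue
            # Frequencies on the same side of 0.5 mean the labeled alleles
            # refer to the same allele regardless of reported strand.
            if (eaf_x - 0.5) * (eaf_y - 0.5) >= 0:
                action = "match"
            else:
                action = "flip"
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
        else:
            pair_y = (ea_y, oa_y)
            comp_y = (_COMPLEMENT.get(ea_y, "?"), _COMPLEMENT.get(oa_y, "?"))
            if pair_y == (ea_x, oa_x) or comp_y == (ea_x, oa_x):
                action = "match"
            elif pair_y == (oa_x, ea_x) or comp_y == (oa_x, ea_x):
                action = "flip"
                beta_y = -beta_y
                if not pd.isna(eaf_y):
                    eaf_y = 1.0 - eaf_y
            else:
                excluded.append((vid, "allele_mismatch"))
                continue

        kept_rows.append(
            {
                "variant_id": vid,
                "beta_exp": float(erow["beta"]),
                "se_exp": float(erow["se"]),
                "beta_out": beta_y,
                "se_out": float(orow["se"]),
                "eaf": float(erow["eaf"]) if not pd.isna(erow["eaf"]) else np.nan,
                "action": action,
            }
        )

    inst = pd.DataFrame(
        kept_rows,
        columns=["variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf", "action"],
    )
    excl = pd.DataFrame(excluded, columns=["variant_id", "reason"])
    counts = {"kept": len(inst)}
    if len(inst):
        counts.update(inst["action"].value_counts().to_dict())
    if len(excl):
        counts.update(excl["reason"].value_counts().to_dict())
    logger.info("harmonize: %s", counts)
    return HarmonizationResult(instruments=inst, excluded=excl, counts=counts)
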