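"""End-to-end analysis: instruments -> harmonization -> estimators -> report.

`run_analysis` reproduces the forest-table layout of a drug-target MR study:
per outcome, every requested estimator with heterogeneity and pleiotropy
diagnostics, leave-one-out, decrement-scaled odds ratios, and a between-
estimate Cochran Q contrast of each primary outcome against the designated
positive control.  All stage artifacts are written to the output directory
as tidy TSVs; the run is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import contrasts as ct
from . import instruments as ins
from . import mr
from . import sumstats as ss

logger = logging.getLogger(__name__)

ALL_METHODS = ["ivw_fixed", "egger", "weighted_median", "weighted_mode"]


@dataclass
class OutcomeSpec:
    path: str
    label: str
    trait_type: str = "binary"
    role: str = "primary"  # primary | positive_control
    column_map: dict | None = None


@dataclass
class AnalysisConfig:
    exposure_path: str
    region: ins.CisRegion
    ld_path: str
    outcomes: list[OutcomeSpec]
    exposure_column_map: dict | None = None
    p_threshold: float = ins.DEFAULT_P_THRESHOLD
    clump_r2: float = ins.DEFAULT_CLUMP_R2
    palindrome_eaf_window: float = 0.08
    decrement_percent: float = 30.0
    methods: list[str] = field(default_factory=lambda: list(ALL_METHODS))
    n_boot: int = 1000
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {ALL_METHODS}")
        n_control = sum(o.role == "positive_control" for o in self.outcomes)
        if n_control > 1:
            raise ValueError("at most one positive_control outcome is allowed")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        region = ins.CisRegion(
            chrom=str(raw["region"]["chrom"]),
            gene_start=int(raw["region"]["gene_start"]),
            gene_end=int(raw["region"]["gene_end"]),
            flank=int(raw["region"].get("flank_bp", ins.DEFAULT_FLANK_BP)),
        )
        outcomes = [OutcomeSpec(**o) for o in raw["outcomes"]]
        kwargs = {
            k: raw[k]
            for k in (
                "p_threshold",
                "clump_r2",
                "palindrome_eaf_window",
                "decrement_percent",
                "methods",
                "n_boot",
                "seed",
                "out_dir",
            )
            if k in raw
        }
        return cls(
            exposure_path=raw["exposure"]["path"],
            exposure_column_map=raw["exposure"].get("column_map"),
            region=region,
            ld_path=raw["ld_matrix"],
            outcomes=outcomes,
            **kwargs,
        )


@dataclass
class AnalysisResult:
    master: pd.DataFrame
    instrument_set: ins.InstrumentSet
    contrasts: pd.DataFrame
    leave_one_out: dict[str, pd.DataFrame]
    out_dir: Path


def _estimate_row(outcome: str, est: mr.MREstimate, scale: float) -> dict:
    scaled = mr.rescale_estimate(est, scale)
    return {
        "outcome": outcome,
        "method": est.method,
        "n_variants": est.n_variants,
        "beta": est.beta,
        "se": est.se,
        "or": scaled.odds_ratio,
        "or_ci_low": scaled.or_ci_low,
        "or_ci_high": scaled.or_ci_high,
        "pvalue": est.pvalue,
    }


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Run the full pipeline; writes stage artifacts under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exposure = ss.read_sumstats(
        config.exposure_path, column_map=config.exposure_column_map, trait_type="quantitative"
    )
    ld = ins.LDMatrix.read(config.ld_path)
    iset = ins.build_instrument_set(
        exposure, config.region, ld, config.p_threshold, config.clump_r2
    )
    if len(iset.table) == 0:
        raise RuntimeError("instrument selection: zero variants survived cis/p/clump filters")
    inst_df = iset.table.df.copy()
    inst_df["f_stat"] = iset.f_stats.to_numpy()
    inst_df.to_csv(out_dir / "instruments.tsv", sep="\t", index=False, na_rep="NA")
    logger.info(
        "instrument set: %d variants, r2_explained=%.4g", len(inst_df), iset.r2_explained
    )

    scale = ins.decrement_scale(config.decrement_percent)
    master_rows: list[dict] = []
    ivw_by_outcome: dict[str, mr.MREstimate] = {}
    loo_by_outcome: dict[str, pd.DataFrame] = {}

    for k, spec in enumerate(config.outcomes):
        outcome_tab = ss.read_sumstats(
            spec.path, column_map=spec.column_map, trait_type=spec.trait_type,
            trait_label=spec.label,
        )
        harm = ss.harmonize(iset.table, outcome_tab, config.palindrome_eaf_window)
        harm.instruments.to_csv(
            out_dir / f"harmonized_{spec.label}.tsv", sep="\t", index=False, na_rep="NA"
        )
        hdf = harm.instruments
        if len(hdf) == 0:
            raise RuntimeError(f"harmonization left zero instruments for {spec.label}")

        if len(hdf) == 1:
            est = mr.wald_ratio(hdf)
            ivw_by_outcome[spec.label] = est
            row = _estimate_row(spec.label, est, scale)
            row.update({"q": float("nan"), "q_df": 0, "q_p": float("nan"),
                        "egger_intercept": float("nan"), "egger_intercept_p": float("nan")})
            master_rows.append(row)
            continue

        ivw = mr.ivw_fixed(hdf)
        ivw_by_outcome[spec.label] = ivw
        qres = mr.cochran_q(hdf, ivw)
        egger = mr.mr_egger(hdf) if len(hdf) >= 3 else None

        for i, method in enumerate(config.methods):
            seed_m = config.seed + 1000 * k + i
            if method == "ivw_fixed":
                est = ivw
            elif method == "egger":
                if egger is None:
                    continue
                est = egger.slope
            elif method == "weighted_median":
                if len(hdf) < 3:
                    continue
                est = mr.weighted_median(hdf, n_boot=config.n_boot, seed=seed_m)
            elif method == "weighted_mode":
                if len(hdf) < 3:
                    continue
                est = mr.weighted_mode(hdf, n_boot=config.n_boot, seed=seed_m)
            row = _estimate_row(spec.label, est, scale)
            row.update(
                {
                    "q": qres.q,
                    "q_df": qres.df,
                    "q_p": qres.pvalue,
                    "egger_intercept": egger.intercept if egger else float("nan"),
                    "egger_intercept_p": egger.intercept_p if egger else float("nan"),
                }
            )
            master_rows.append(row)

        if len(hdf) >= 3:
            loo = mr.leave_one_out(hdf)
            loo.to_csv(out_dir / f"leave_one_out_{spec.label}.tsv", sep="\t", index=False)
            loo_by_outcome[spec.label] = loo

    master = pd.DataFrame(master_rows)
    n_primary = sum(o.role == "primary" for o in config.outcomes)
    if n_primary:
        master["bonferroni_threshold"] = 0.05 / n_primary
        master["significant_bonferroni"] = master["pvalue"] < 0.05 / n_primary

    control = [o for o in config.outcomes if o.role == "positive_control"]
    contrast_rows = []
    if control:
        ref = ivw_by_outcome[control[0].label]
        for spec in config.outcomes:
            if spec.role != "primary":
                continue
            qc = ct.between_estimate_q(ivw_by_outcome[spec.label], ref)
            contrast_rows.append(
                {
                    "outcome": spec.label,
                    "reference": control[0].label,
                    "q": qc.q,
                    "df": qc.df,
                    "pvalue": qc.pvalue,
                }
            )
    contrasts_df = pd.DataFrame(contrast_rows)

    master.to_csv(out_dir / "master.tsv", sep="\t", index=False, na_rep="NA")
    if len(contrasts_df):
        contrasts_df.to_csv(out_dir / "contrasts.tsv", sep="\t", index=False)
    (out_dir / "report.md").write_text(render_forest_table(master, contrasts_df))
    return AnalysisResult(
        master=master,
        instrument_set=iset,
        contrasts=contrasts_df,
        leave_one_out=loo_by_outcome,
        out_dir=out_dir,
    )


def render_forest_table(master: pd.DataFrame, contrasts: pd.DataFrame | None = None) -> str:
    """Markdown forest-style table: one row per outcome x method."""
    if master.empty:
        logger.warning("render_forest_table: empty master table")
        return "(no estimates)\n"
    lines = [
        "| Outcome | Method | N variants | OR (95% CI) | P | Het. Q (p) | Egger intercept p |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, row in master.iterrows():
        or_txt = f"{row['or']:.2f} ({row['or_ci_low']:.2f}, {row['or_ci_high']:.2f})"
        q_txt = "-" if pd.isna(row["q"]) else f"{row['q']:.2f} ({row['q_p']:.3g})"
        e_txt = (
            "-"
            if pd.isna(row["egger_intercept_p"])
            else f"{row['egger_intercept_p']:.3g}"
        )
        lines.append(
            f"| {row['outcome']} | {row['method']} | {row['n_variants']} | {or_txt} "
            f"| {row['pvalue']:.3g} | {q_txt} | {e_txt} |"
        )
    text = "\n".join(lines) + "\n"
    if contrasts is not None and len(contrasts):
        text += "\nBetween-estimate heterogeneity vs positive control:\n\n"
        text += "| Outcome | Reference | Q | p |\n|---|---|---|---|\n"
        for row in contrasts.itertuples(index=False):
            text += f"| {row.outcome} | {row.reference} | {row.q:.2f} | {row.pvalue:.3g} |\n"
    return text


def config_to_yaml(config: AnalysisConfig, path) -> None:
    """Persist a config (for provenance alongside the outputs)."""
    raw = dataclasses.asdict(config)
    raw["region"] = dataclasses.asdict(config.region)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
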