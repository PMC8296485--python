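"""End-to-end orchestration: simulate/load -> split -> fit -> score -> validate.

Produces a :class:`StudyReport` whose tables mirror the usual reporting
layout of a prevalence risk-index study: factor descriptives with
chi-square comparisons, the regression table, the score model, risk-level
strata per group, the cut-point table and ROC summaries.  Rendering is
deterministic; a manifest records the seed and configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import MODEL_FACTORS, RiskFactorProfile, Sex, read_profiles_csv
from .index import (
    DEFAULT_BANDS,
    DEFAULT_EXPOSURES,
    ExposureRegistry,
    RiskAssessment,
    RiskLevel,
    RiskScoreModel,
    ScoreBand,
    ScoreBandTable,
    achievable_r_grid,
    assess_profile,
    build_score_model,
)
from .regression import RegressionResult, TwoByTwoTable, crude_chi2, fit_poisson_log_binary
from .simulate import GeneratorConfig, generate_cohort, split_modeling_validation
from .validation import (
    CutpointRow,
    ROCResult,
    RankSumResult,
    TrendTestResult,
    cutpoint_table,
    optimal_cutoff,
    ranksum_ordinal,
    roc_auc,
    trend_chi2,
)

logger = logging.getLogger("cvdrisk")

__all__ = ["PipelineConfig", "StudyReport", "PipelineError", "run_pipeline", "render_report"]

_DESCRIPTIVE_FACTORS = (
    "age_ge_60",
    "lack_of_exercise",
    "smoking",
    "hypertension",
    "diabetes",
    "family_history_cvd",
    "alcohol",
    "obesity",
    "dyslipidemia",
    "cardiopathy",
)


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline parameterization; either simulate a cohort or load one."""

    n: int = 2138
    seed: int = 0
    profiles_csv: Optional[str] = None  # load instead of simulate when set
    factors: tuple[str, ...] = MODEL_FACTORS
    generator: GeneratorConfig | None = None
    registry: ExposureRegistry = DEFAULT_EXPOSURES
    bands: ScoreBandTable = DEFAULT_BANDS

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("n", "seed", "profiles_csv"):
            if key in raw:
                kwargs[key] = raw[key]
        if "factors" in raw:
            kwargs["factors"] = tuple(raw["factors"])
        gen_keys = {"marginals", "intercept", "coefficients", "p_cap"}
        if gen_keys & raw.keys():
            kwargs["generator"] = GeneratorConfig(
                n=raw.get("n", 2138),
                seed=raw.get("seed", 0),
                **{k: raw[k] for k in gen_keys if k in raw},
            )
        if "exposure_rates" in raw:
            kwargs["registry"] = ExposureRegistry(
                rates=raw["exposure_rates"], sources=raw.get("exposure_sources", {})
            )
        if "bands" in raw:
            kwargs["bands"] = ScoreBandTable(
                bands=tuple(
                    ScoreBand(b["lo"], float(b["hi"]), b["score"]) for b in raw["bands"]
                )
            )
        return cls(**kwargs)


@dataclass
class StudyReport:
    """All rendered tables; every number traceable to a module output."""

    descriptive: pd.DataFrame
    regression: RegressionResult
    score_model: RiskScoreModel
    risk_levels: pd.DataFrame
    cutpoints: list[CutpointRow]
    optimal: Optional[CutpointRow]
    roc_total: Optional[ROCResult]
    roc_by_sex: dict[str, ROCResult] = field(default_factory=dict)
    sex_auc_p: Optional[float] = None
    trend: dict[str, TrendTestResult] = field(default_factory=dict)
    ranksum_modeling_vs_validation: Optional[RankSumResult] = None
    manifest: dict = field(default_factory=dict)


def _descriptive_table(profiles: list[RiskFactorProfile]) -> pd.DataFrame:
    rows = []
    for factor in _DESCRIPTIVE_FACTORS:
        flags = np.array([getattr(p, factor) for p in profiles], dtype=bool)
        cases = np.array([p.cvd_case for p in profiles], dtype=bool)
        n_exp = int(flags.sum())
        n_unexp = int((~flags).sum())
        row = {
            "factor": factor,
            "n_exposed": n_exp,
            "n_unexposed": n_unexp,
            "prev_exposed_pct": round(100 * cases[flags].mean(), 1) if n_exp else np.nan,
            "prev_unexposed_pct": round(100 * cases[~flags].mean(), 1) if n_unexp else np.nan,
        }
        try:
            table = TwoByTwoTable(
                exposed_cases=int(cases[flags].sum()),
                exposed_noncases=int((~cases[flags]).sum()),
                unexposed_cases=int(cases[~flags].sum()),
                unexposed_noncases=int((~cases[~flags]).sum()),
            )
            chi2, p = crude_chi2(table)
            row["chi2"], row["p"] = round(chi2, 3), p
        except ValueError:
            row["chi2"], row["p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _level_table(assessments: dict[str, list[RiskAssessment]],
                 outcomes: dict[str, list[bool]]) -> pd.DataFrame:
    rows = []
    for group, assess in assessments.items():
        cases = outcomes[group]
        for level in RiskLevel:
            idx = [i for i, a in enumerate(assess) if a.level is level]
            n = len(idx)
            ill = sum(cases[i] for i in idx)
            rows.append(
                {
                    "group": group,
                    "level": level.label,
                    "n_enrolled": n,
                    "n_ill": ill,
                    "prevalence_pct": round(100 * ill / n, 1) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Run the full pipeline; reproducible given the seed."""
    # --- cohort -----------------------------------------------------------
    try:
        if config.profiles_csv is not None:
            profiles = read_profiles_csv(config.profiles_csv)
            logger.info("loaded %d profiles from %s", len(profiles), config.profiles_csv)
            manifest_source = {"profiles_csv": str(config.profiles_csv)}
            n_capped = None
        else:
            gen = config.generator or GeneratorConfig(n=config.n, seed=config.seed)
            cohort = generate_cohort(gen)
            profiles = cohort.profiles
            n_capped = cohort.n_capped
            logger.info(
                "simulated %d profiles (prevalence %.3f, %d capped patterns)",
                len(profiles), cohort.realized_prevalence, cohort.n_capped,
            )
            manifest_source = {"generator_seed": gen.seed, "n": gen.n}
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        raise PipelineError("cohort", str(exc)) from exc

    # --- split ------------------------------------------------------------
    try:
        modeling, validation = split_modeling_validation(profiles)
        logger.info("split: modeling n=%d, validation n=%d", len(modeling), len(validation))
    except Exception as exc:
        raise PipelineError("split", str(exc)) from exc

    # --- fit --------------------------------------------------------------
    try:
        y = np.array([p.cvd_case for p in modeling], dtype=float)
        X = np.array([[getattr(p, f) for f in config.factors] for p in modeling], dtype=float)
        regression = fit_poisson_log_binary(y, X, names=list(config.factors))
        if not regression.converged:
            logger.warning("regression did not converge in %d iterations", regression.iterations)
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    # --- score model ------------------------------------------------------
    try:
        score_model = build_score_model(
            regression.or_map(), config.registry, config.bands,
            provenance="modeling-group fit",
        )
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc

    # --- assess both halves ----------------------------------------------
    try:
        assess_mod = [assess_profile(p, score_model) for p in modeling]
        assess_val = [assess_profile(p, score_model) for p in validation]
    except Exception as exc:
        raise PipelineError("assess", str(exc)) from exc

    # --- validate on the validation half ---------------------------------
    cutpoints: list[CutpointRow] = []
    optimal = None
    roc_total = None
    roc_by_sex: dict[str, ROCResult] = {}
    sex_auc_p = None
    trend: dict[str, TrendTestResult] = {}
    ranksum = None
    try:
        r_val = [a.r for a in assess_val]
        y_val = [p.cvd_case for p in validation]
        grid = achievable_r_grid(score_model)
        if any(y_val) and not all(y_val):
            cutpoints = cutpoint_table(r_val, y_val, grid)
            optimal = optimal_cutoff(cutpoints)
            roc_total = roc_auc(r_val, y_val)
            from .validation import compare_auc  # local to keep the top import block tidy

            by_sex_vals = {}
            for sex in (Sex.MALE, Sex.FEMALE):
                idx = [i for i, p in enumerate(validation) if p.sex is sex]
                vv = [r_val[i] for i in idx]
                yy = [y_val[i] for i in idx]
                if any(yy) and not all(yy):
                    roc_by_sex[sex.value] = roc_auc(vv, yy)
                    by_sex_vals[sex.value] = (vv, yy)
            if len(by_sex_vals) == 2:
                (va, ya), (vb, yb) = by_sex_vals["male"], by_sex_vals["female"]
                _, sex_auc_p = compare_auc(va, ya, vb, yb)
        else:
            logger.warning("validation half has a single outcome class; skipping "
                           "cut-point and ROC tables")

        level_outcomes = {
            "modeling": [p.cvd_case for p in modeling],
            "validation_predicted": y_val,
        }
        level_assess = {"modeling": assess_mod, "validation_predicted": assess_val}
        levels_df = _level_table(level_assess, level_outcomes)
        for group in level_assess:
            sub = levels_df[levels_df.group == group]
            counts = [(int(r.n_enrolled), int(r.n_ill)) for r in sub.itertuples()]
            if sum(1 for n, _ in counts if n > 0) >= 2 and any(y for y in level_outcomes[group]):
                trend[group] = trend_chi2(counts)
        ranksum = ranksum_ordinal(
            [int(a.level) for a in assess_mod], [int(a.level) for a in assess_val]
        )
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc

    # --- report -----------------------------------------------------------
    try:
        descriptive = _descriptive_table(profiles)
        cfg_repr = repr(config).encode()
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_repr).hexdigest(),
            "n_total": len(profiles),
            "n_modeling": len(modeling),
            "n_validation": len(validation),
            "n_capped_patterns": n_capped,
            **manifest_source,
        }
        return StudyReport(
            descriptive=descriptive,
            regression=regression,
            score_model=score_model,
            risk_levels=levels_df,
            cutpoints=cutpoints,
            optimal=optimal,
            roc_total=roc_total,
            roc_by_sex=roc_by_sex,
            sex_auc_p=sex_auc_p,
            trend=trend,
            ranksum_modeling_vs_validation=ranksum,
            manifest=manifest,
        )
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc


def _pct(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(100 * x, 1)


def _cutpoint_frame(cutpoints: list[CutpointRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cutoff_r": round(c.cutoff_r, 2),
                "sensitivity_pct": _pct(c.sensitivity),
                "specificity_pct": _pct(c.specificity),
                "youden": round(c.youden, 3),
                "ppv_pct": _pct(c.ppv),
                "npv_pct": _pct(c.npv),
            }
            for c in cutpoints
        ]
    )


def report_to_dict(report: StudyReport) -> dict:
    """JSON-ready dictionary with the same numbers as every other rendering."""
    d = {
        "manifest": report.manifest,
        "descriptive": report.descriptive.to_dict(orient="records"),
        "regression": report.regression.to_dict(),
        "score_model": json.loads(report.score_model.to_json()),
        "risk_levels": report.risk_levels.to_dict(orient="records"),
        "cutpoints": _cutpoint_frame(report.cutpoints).to_dict(orient="records"),
    }
    if report.optimal is not None:
        d["optimal_cutoff"] = {
            "cutoff_r": round(report.optimal.cutoff_r, 2),
            "sensitivity_pct": _pct(report.optimal.sensitivity),
            "specificity_pct": _pct(report.optimal.specificity),
            "youden": round(report.optimal.youden, 3),
        }
    if report.roc_total is not None:
        d["roc"] = {
            "total": _roc_dict(report.roc_total),
            **{k: _roc_dict(v) for k, v in report.roc_by_sex.items()},
        }
        if report.sex_auc_p is not None:
            d["roc"]["sex_comparison_p"] = round(report.sex_auc_p, 3)
    if report.trend:
        d["trend_chi2"] = {
            k: {"chi2": round(v.chi2_trend, 3), "p": v.p_value} for k, v in report.trend.items()
        }
    if report.ranksum_modeling_vs_validation is not None:
        rs = report.ranksum_modeling_vs_validation
        d["ranksum_modeling_vs_validation"] = {"z": round(rs.z, 3), "p": round(rs.p_value, 3)}
    return d


def _roc_dict(r: ROCResult) -> dict:
    return {
        "auc": round(r.auc, 3),
        "ci_low": round(r.ci_low, 3),
        "ci_high": round(r.ci_high, 3),
        "n_cases": r.n_cases,
        "n_controls": r.n_controls,
    }


def render_report(report: StudyReport, out_dir, fmt: str = "csv_bundle") -> list[Path]:
    """Write the report as a CSV bundle, JSON document, or markdown file.

    Returns the written paths.  All formats carry identical numbers.
    Empty validation tables are omitted with a logged notice.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = report_to_dict(report)
    written: list[Path] = []
    if fmt == "json":
        p = out / "report.json"
        p.write_text(json.dumps(d, indent=2, default=float))
        written.append(p)
    elif fmt == "csv_bundle":
        for name, frame in (
            ("descriptive", pd.DataFrame(d["descriptive"])),
            ("regression", pd.DataFrame(d["regression"]["terms"])),
            ("risk_levels", pd.DataFrame(d["risk_levels"])),
        ):
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False)
            written.append(p)
        if d["cutpoints"]:
            p = out / "cutpoints.csv"
            pd.DataFrame(d["cutpoints"]).to_csv(p, index=False)
            written.append(p)
        else:
            logger.info("cut-point table empty; not rendered")
        p = out / "summary.json"
        summary = {k: v for k, v in d.items()
                   if k in ("manifest", "score_model", "optimal_cutoff", "roc",
                            "trend_chi2", "ranksum_modeling_vs_validation")}
        p.write_text(json.dumps(summary, indent=2, default=float))
        written.append(p)
    elif fmt == "markdown":
        p = out / "report.md"
        p.write_text(_render_markdown(d))
        written.append(p)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return written


def _render_markdown(d: dict) -> str:
    lines = ["# Risk-index study report", ""]
    lines += ["## Manifest", "```json", json.dumps(d["manifest"], indent=2, default=float), "```", ""]

    def table(records: list[dict]) -> list[str]:
        if not records:
            return ["(empty)", ""]
        cols = list(records[0])
        out = ["| " + " | ".join(cols) + " |",
               "| " + " | ".join("---" for _ in cols) + " |"]
        for rec in records:
            out.append("| " + " | ".join(str(rec[c]) for c in cols) + " |")
        out.append("")
        return out

    lines += ["## Factor descriptives"] + table(d["descriptive"])
    lines += ["## Regression"] + table(d["regression"]["terms"])
    sm_records = [
        {"factor": f, "score": s, "exposure_rate": d["score_model"]["exposure_rates"][f]}
        for f, s in d["score_model"]["scores"].items()
    ]
    lines += ["## Score model (AROP = %s)" % round(d["score_model"]["arop"], 2)] + table(sm_records)
    lines += ["## Risk levels"] + table(d["risk_levels"])
    if d["cutpoints"]:
        lines += ["## Cut-points"] + table(d["cutpoints"])
    else:
        lines += ["## Cut-points", "(omitted: empty validation stage)", ""]
        logger.info("cut-point table empty; omitted from markdown report")
    for key in ("optimal_cutoff", "roc", "trend_chi2", "ranksum_modeling_vs_validation"):
        if key in d:
            lines += [f"## {key}", "```json", json.dumps(d[key], indent=2, default=float), "```", ""]
    return "\n".join(lines)
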