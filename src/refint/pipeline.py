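"""End-to-end indirect reference-interval workflow and report assembly.

Order of operations, mirroring the indirect method: clean the raw extract;
test whether the sexes differ (Harris-Boyd, on the Box-Cox scale by
default) and split if so; quantify the age trend per sex (Spearman); test
the female age split at the configured break; then, per reported subgroup,
transform / check symmetry / iteratively delete Tukey outliers and compute
both 95% reference-interval routes with 90% CIs.  Partition verdicts GATE
the grouping unless ``force_groups`` is set.

The run report is a plain (JSON-serialisable) dict; ``write_report`` emits
``report.json`` plus a flat ``ri_table.csv``.  Everything is deterministic
for a fixed input and configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ingest
from .intervals import GroupResult, ReferenceInterval, build_ri_table
from .partition import PartitionDecision, decide_partition, spearman_rho
from .transform import DEFAULT_LAMBDA_BOUNDS

__all__ = ["RunConfig", "run_pipeline", "write_report", "report_to_jsonable"]

#: smallest subgroup on which transformation + outlier deletion is attempted
MIN_GROUP_N = 40


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    input: str | None = None
    columns: dict = field(default_factory=dict)       # canonical -> file header
    pregnant_column: str | None = None
    detection_limits: tuple[float, float] = (1.0, 2000.0)
    age_break: int = 50
    alpha: float = 0.05
    lambda_bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS
    max_outlier_iterations: int = 20
    partition_scale: str = "transformed"              # or "raw"
    partition_crit_n: str = "pre_outlier"             # or "post_outlier"
    force_groups: bool = False
    round_nonparametric: bool = False
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        lo, hi = self.detection_limits
        if not lo < hi:
            raise ValueError("detection_limits must be increasing")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.partition_scale not in ("transformed", "raw"):
            raise ValueError("partition_scale must be 'transformed' or 'raw'")
        if self.partition_crit_n not in ("pre_outlier", "post_outlier"):
            raise ValueError("partition_crit_n must be 'pre_outlier' or 'post_outlier'")
        if self.max_outlier_iterations < 1:
            raise ValueError("max_outlier_iterations must be >= 1")
        if not self.lambda_bounds[0] < self.lambda_bounds[1]:
            raise ValueError("lambda_bounds must be increasing")


def run_pipeline(config: RunConfig, raw: pd.DataFrame | None = None) -> dict:
    """Run the full indirect-RI workflow; returns the run report dict.

    ``raw`` bypasses file reading (a raw, string-typed table as the
    generator produces); otherwise ``config.input`` is loaded.
    """
    config.validate()
    if raw is not None:
        records = ingest.parse_raw_frame(raw, columns=config.columns or None,
                                         pregnant_column=config.pregnant_column)
    elif config.input is not None:
        records = ingest.load_records(config.input, columns=config.columns or None,
                                      pregnant_column=config.pregnant_column)
    else:
        raise ValueError("no input: set config.input or pass a raw frame")

    lo, hi = config.detection_limits
    cleaned, cleaning = ingest.clean(records, low=lo, high=hi)

    males = cleaned.loc[cleaned["sex"] == "male"]
    females = cleaned.loc[cleaned["sex"] == "female"]

    report: dict = {
        "config": dataclasses.asdict(config),
        "cleaning": cleaning.to_dict(),
        "correlations": {},
        "partitions": {},
    }

    # age trend per sex (Spearman, raw values: rank-based so scale-free)
    for name, sub in (("males", males), ("females", females)):
        if len(sub) >= 10 and sub["age"].nunique() > 1:
            res = spearman_rho(sub["age"].to_numpy(float), sub["value"].to_numpy(float))
            report["correlations"][name] = dataclasses.asdict(res)

    def crit_ns(v1: np.ndarray, v2: np.ndarray) -> tuple[int, int]:
        # z* is conventionally computed from the pre-outlier-deletion sizes;
        # the post_outlier switch uses the deleted-sample sizes instead.
        if config.partition_crit_n == "pre_outlier":
            return v1.size, v2.size
        from .outliers import remove_outliers_iterative
        return (remove_outliers_iterative(v1, max_iter=config.max_outlier_iterations,
                                          lambda_bounds=config.lambda_bounds).final_values.size,
                remove_outliers_iterative(v2, max_iter=config.max_outlier_iterations,
                                          lambda_bounds=config.lambda_bounds).final_values.size)

    sex_split = False
    if len(males) >= MIN_GROUP_N and len(females) >= MIN_GROUP_N:
        mv = males["value"].to_numpy(float)
        fv = females["value"].to_numpy(float)
        sex_dec = decide_partition(
            mv, fv,
            scale=config.partition_scale,
            crit_ns=crit_ns(mv, fv),
            lambda_bounds=config.lambda_bounds,
        )
        report["partitions"]["male_vs_female"] = dataclasses.asdict(sex_dec)
        sex_split = sex_dec.separate
    elif len(males) >= MIN_GROUP_N or len(females) >= MIN_GROUP_N:
        sex_split = True  # single-sex cohort: report that sex on its own

    female_age_split = False
    fy = females.loc[females["age"] < config.age_break]
    fo = females.loc[females["age"] >= config.age_break]
    if len(fy) >= MIN_GROUP_N and len(fo) >= MIN_GROUP_N:
        fyv = fy["value"].to_numpy(float)
        fov = fo["value"].to_numpy(float)
        age_dec = decide_partition(
            fyv, fov,
            scale=config.partition_scale,
            crit_ns=crit_ns(fyv, fov),
            lambda_bounds=config.lambda_bounds,
        )
        report["partitions"]["female_age"] = dataclasses.asdict(age_dec)
        female_age_split = age_dec.separate

    if config.force_groups:
        sex_split = female_age_split = True

    groups = build_ri_table(
        cleaned,
        sex_split=sex_split,
        female_age_split=female_age_split,
        age_break=config.age_break,
        alpha=config.alpha,
        max_iter=config.max_outlier_iterations,
        lambda_bounds=config.lambda_bounds,
        round_nonparametric=config.round_nonparametric,
    )
    report["groups"] = [_group_to_dict(g) for g in groups]
    return report


def _ri_to_dict(ri: ReferenceInterval) -> dict:
    d = dataclasses.asdict(ri)
    # Table-style presentation rounds to 2 decimals; raw values kept too
    d["display"] = {
        "ri": f"{ri.lower:.2f}-{ri.upper:.2f}",
        "ll_90ci": f"{ri.lower_ci[0]:.2f}-{ri.lower_ci[1]:.2f}",
        "ul_90ci": f"{ri.upper_ci[0]:.2f}-{ri.upper_ci[1]:.2f}",
    }
    return d


def _group_to_dict(g: GroupResult) -> dict:
    return {
        "name": g.name,
        "n": g.n,
        "outliers": {
            "n_iterations": g.outliers.n_iterations,
            "total_removed": g.outliers.total_removed,
            "final_n": int(g.outliers.final_values.size),
            "final_lambda": g.outliers.final_lambda,
            "converged": g.outliers.converged,
            "iterations": [dataclasses.asdict(it) for it in g.outliers.iterations],
        },
        "distribution": {
            "before": dataclasses.asdict(g.dist_before),
            "before_transformed": dataclasses.asdict(g.dist_before_transformed),
            "after": dataclasses.asdict(g.dist_after),
            "after_transformed": dataclasses.asdict(g.dist_after_transformed),
        },
        "parametric": _ri_to_dict(g.parametric),
        "nonparametric": _ri_to_dict(g.nonparametric),
    }


def report_to_jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dumps accepts them."""
    if isinstance(obj, dict):
        return {k: report_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [report_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: dict, outdir) -> None:
    """Write ``report.json`` and the flat ``ri_table.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report_to_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    rows = []
    for g in report.get("groups", []):
        for method in ("parametric", "nonparametric"):
            ri = g[method]
            rows.append({
                "group": g["name"],
                "method": method,
                "n": ri["n"],
                "lambda": ri["lam"],
                "lower": ri["lower"],
                "upper": ri["upper"],
                "ll_ci_low": ri["lower_ci"][0],
                "ll_ci_high": ri["lower_ci"][1],
                "ul_ci_low": ri["upper_ci"][0],
                "ul_ci_high": ri["upper_ci"][1],
            })
    pd.DataFrame(rows).to_csv(outdir / "ri_table.csv", index=False,
                              float_format="%.4f", lineterminator="\n")
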