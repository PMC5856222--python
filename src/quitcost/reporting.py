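"""Publication-shaped tables, run configuration and the end-to-end pipeline.

``render_summary_table`` is the cohort-composition table (per factor band:
N, percent of the non-missing total, quits, quit percent);
``render_cpq_table`` is the cost-per-quit table (N, total cost, cost per
head, quits, quit rate, mean CPQ with its bootstrap interval).
``run_pipeline`` chains read -> exclude -> cost -> label -> estimate ->
report and writes machine-readable artifacts plus a manifest that fully
determines them: rerunning with the same config and seed reproduces the
same bytes.

Machine outputs (CSV/JSON/YAML) never contain thousands separators; those
appear only in the human-readable text rendering.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .costing import cost_records, load_cost_config
from .cpq import BootstrapConfig, CPQEstimate, overall_estimate, subgroup_table
from .errors import ConfigurationError
from .records import (DEFAULT_CUTOFF, ServiceRecord, apply_exclusions,
                      read_records)
from .roi import (DEFAULT_BASELINE, DEFAULT_RELATIVE_RATES, derive_scenario)
from .subgroups import FACTOR_NAMES, FACTORS, SubgroupLabels, label_records

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("factor", "level", "n", "pct", "n_quit", "quit_pct")
CPQ_COLUMNS = ("level", "n", "total_cost", "cost_per_head", "n_quits",
               "quit_rate", "mean_cpq", "ci_lower", "ci_upper")


@dataclass
class AnalysisConfig:
    """Everything one pipeline run depends on.

    ``column_map`` remaps logical field names to input column names;
    ``costs_path`` optionally overrides the packaged unit-cost file;
    ``relative_rates`` and ``baseline`` parameterise the ROI scenario.
    """

    input_path: str
    out_dir: str
    factors: tuple[str, ...] = FACTOR_NAMES
    column_map: dict[str, str] = field(default_factory=dict)
    cutoff_date: datetime.date = DEFAULT_CUTOFF
    costs_path: str | None = None
    n_replicates: int = 1000
    seed: int = 0
    relative_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELATIVE_RATES))
    baseline: float = DEFAULT_BASELINE
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.factors) - set(FACTORS)
        if unknown:
            raise ConfigurationError(f"unknown factor(s): {sorted(unknown)}")
        self.factors = tuple(self.factors)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoff_date"] = self.cutoff_date.isoformat()
        d["factors"] = list(self.factors)
        return d

    @classmethod
    def from_dict(cls, doc: Mapping) -> "AnalysisConfig":
        d = dict(doc)
        if isinstance(d.get("cutoff_date"), str):
            d["cutoff_date"] = datetime.date.fromisoformat(d["cutoff_date"])
        if "factors" in d:
            d["factors"] = tuple(d["factors"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(f"bad config: {exc}") from None

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "AnalysisConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def render_summary_table(
    records: Sequence[ServiceRecord],
    labels: Sequence[SubgroupLabels],
    factors: Sequence[str] = FACTOR_NAMES,
) -> pd.DataFrame:
    """Cohort composition and quit rates per factor band.

    Percentages use the factor's non-missing record count as denominator,
    so a factor with missing values has band Ns summing below the cohort N
    but percentages summing to 100.
    """
    rows = []
    for factor in factors:
        accessor, bands = FACTORS[factor]
        present = [(r, l) for r, l in zip(records, labels)
                   if accessor(l) is not None]
        denom = len(present)
        for band in bands:
            group = [r for r, l in present if accessor(l) == band]
            if not group:
                continue
            n_quit = sum(r.quit_12wk for r in group)
            rows.append({
                "factor": factor,
                "level": band,
                "n": len(group),
                "pct": round(100.0 * len(group) / denom, 1),
                "n_quit": n_quit,
                "quit_pct": round(100.0 * n_quit / len(group), 1),
            })
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def render_cpq_table(estimates: Sequence[CPQEstimate]) -> pd.DataFrame:
    """The CPQ table: money and rates to 2 decimal places."""
    rows = [{
        "level": e.label,
        "n": e.n,
        "total_cost": round(e.total_cost, 2),
        "cost_per_head": round(e.cost_per_head, 2),
        "n_quits": e.n_quits,
        "quit_rate": round(e.quit_rate, 2),
        "mean_cpq": round(e.mean_cpq, 2),
        "ci_lower": round(e.ci_lower, 2),
        "ci_upper": round(e.ci_upper, 2),
    } for e in estimates]
    return pd.DataFrame(rows, columns=list(CPQ_COLUMNS))


def format_cpq_table(frame: pd.DataFrame) -> str:
    """Human-readable rendering with thousands separators and a combined
    "mean CPQ (95% CI)" column."""
    if frame.empty:
        return " | ".join(["level", "n", "total_cost", "cost_per_head",
                           "n_quits", "quit_rate", "mean_cpq_ci"])
    disp = pd.DataFrame({
        "level": frame["level"],
        "n": frame["n"].map("{:,}".format),
        "total_cost": frame["total_cost"].map("{:,.2f}".format),
        "cost_per_head": frame["cost_per_head"].map("{:,.2f}".format),
        "n_quits": frame["n_quits"].map("{:,}".format),
        "quit_rate": frame["quit_rate"].map("{:.2f}".format),
        "mean_cpq_ci": [
            f"{m:,.2f} ({lo:,.2f}, {hi:,.2f})"
            for m, lo, hi in zip(frame["mean_cpq"], frame["ci_lower"],
                                 frame["ci_upper"])
        ],
    })
    return disp.to_string(index=False)


def run_pipeline(config: AnalysisConfig) -> dict[str, Path]:
    """Execute the full analysis and write its artifacts.

    Writes, under ``config.out_dir``: ``summary.csv``, ``cpq_overall.csv``,
    ``cpq_<factor>.csv`` per requested factor, ``exclusions.json``,
    ``scenario.yaml`` and ``manifest.json``.  Returns the artifact paths.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    in_path = Path(config.input_path)
    if not in_path.exists():
        raise ConfigurationError(f"input file not found: {in_path}")
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage read: %s", in_path)
    records = read_records(str(in_path), column_map=config.column_map or None)

    logger.info("stage exclude: cutoff %s", config.cutoff_date)
    retained, report = apply_exclusions(records, config.cutoff_date)

    logger.info("stage cost: %d records", len(retained))
    if config.costs_path:
        rate, schedules = load_cost_config(config.costs_path)
    else:
        rate, schedules = None, None
    costed = cost_records(retained, rate, schedules)

    logger.info("stage label")
    labels = label_records(retained)

    boot = BootstrapConfig(n_replicates=config.n_replicates, seed=config.seed)
    logger.info("stage estimate: overall + %d factor(s), %d replicates",
                len(config.factors), boot.n_replicates)
    paths: dict[str, Path] = {}

    overall = overall_estimate(costed, boot)
    paths["cpq_overall"] = out_dir / "cpq_overall.csv"
    render_cpq_table([overall]).to_csv(paths["cpq_overall"], index=False)
    for factor in config.factors:
        table = subgroup_table(costed, labels, factor, boot)
        paths[f"cpq_{factor}"] = out_dir / f"cpq_{factor}.csv"
        render_cpq_table(table).to_csv(paths[f"cpq_{factor}"], index=False)

    logger.info("stage report")
    paths["summary"] = out_dir / "summary.csv"
    render_summary_table(retained, labels, config.factors).to_csv(
        paths["summary"], index=False)

    paths["exclusions"] = out_dir / "exclusions.json"
    paths["exclusions"].write_text(report.to_json() + "\n")

    scenario = derive_scenario(costed, config.relative_rates, config.baseline)
    paths["scenario"] = out_dir / "scenario.yaml"
    with open(paths["scenario"], "w") as fh:
        scenario.to_yaml(fh)

    manifest = {
        "package": "quitcost",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_input": report.n_input,
        "n_retained": report.n_retained,
    }
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d artifacts in %s", len(paths), out_dir)
    return paths
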