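"""End-to-end pipeline: data -> fit -> simulate -> summarize -> sensitivity.

Ties the stages together the way the source analysis ran them: obtain an
infusion dataset (synthetic or CSV), fit a triangular concentration
distribution per tea type from the pooled measurements across brewing times,
combine it with per-age-group exposure distributions, run the seeded Monte
Carlo, and write summaries, per-iteration draws, sensitivity tables and one
combined wide table (rows = product type, columns = age group x digest).

The default exposure distributions shipped here are plausible
reconstructions for a tea-drinking population (see docs/methods.md for the
rationale behind each); they are the package's own choices, not values lifted
from any external table, and each block can be overridden from the YAML
config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import distributions as dist
from .data import InfusionDataset, read_infusion_csv, write_infusion_csv
from .errors import FluoriskError, ValidationError
from .risk import AGE_GROUPS, DEFAULT_RFD, ExposureScenario, run_monte_carlo, summarize
from .sensitivity import contribution_to_variance, sensitivity_narrative
from .stats import group_summaries, pairwise_type_comparisons
from .synthetic import StudyDesign, default_study_design, generate_infusion_study

__all__ = [
    "RunConfig",
    "default_exposure_blocks",
    "build_scenarios",
    "run_pipeline",
    "load_config",
]

logger = logging.getLogger("fluorisk")


def default_exposure_blocks() -> dict[str, dict[str, Any]]:
    """Per-age-group exposure distributions (DI, EF, ED, BW) and RfD.

    Triangular intake and body-weight distributions with uniform exposure
    duration spanning each group's age range; exposure frequency is shared
    across groups (tea drunk most days, up to daily). Units: DI L/day,
    EF days/year, ED years, BW kg, RfD mg/kg/day.
    """
    ef = {"family": "triangular", "a": 180.0, "c": 365.0, "b": 365.0}
    return {
        "children": {
            "DI": {"family": "triangular", "a": 0.15, "c": 0.25, "b": 0.4},
            "EF": dict(ef),
            "ED": {"family": "uniform", "low": 1.0, "high": 10.0},
            "BW": {"family": "triangular", "a": 14.0, "c": 18.0, "b": 25.0},
            "rfd": DEFAULT_RFD["children"],
        },
        "teenagers": {
            "DI": {"family": "triangular", "a": 0.25, "c": 0.4, "b": 0.6},
            "EF": dict(ef),
            "ED": {"family": "uniform", "low": 11.0, "high": 20.0},
            "BW": {"family": "triangular", "a": 40.0, "c": 52.0, "b": 65.0},
            "rfd": DEFAULT_RFD["teenagers"],
        },
        "adults": {
            "DI": {"family": "triangular", "a": 0.4, "c": 0.8, "b": 1.2},
            "EF": dict(ef),
            "ED": {"family": "uniform", "low": 21.0, "high": 70.0},
            "BW": {"family": "triangular", "a": 50.0, "c": 62.0, "b": 80.0},
            "rfd": DEFAULT_RFD["adults"],
        },
    }


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: Path
    seed: int = 0
    n_iterations: int = 10_000
    infusion_csv: Path | None = None
    design: StudyDesign | None = None
    exposure: Mapping[str, Mapping[str, Any]] = field(default_factory=default_exposure_blocks)
    percentiles: tuple[float, ...] = (5.0, 95.0)
    pool_brew_times: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError(f"n_iterations must be >= 1, got {self.n_iterations}")
        for p in self.percentiles:
            if not 0 < p < 100:
                raise ValidationError(f"percentiles must lie in (0, 100), got {p}")
        for group in self.exposure:
            if group not in AGE_GROUPS:
                raise ValidationError(f"unknown age group {group!r} in exposure config")

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "n_iterations": self.n_iterations,
            "infusion_csv": str(self.infusion_csv) if self.infusion_csv else None,
            "design_seed": self.design.seed if self.design else None,
            "exposure": {k: dict(v) for k, v in self.exposure.items()},
            "percentiles": list(self.percentiles),
            "pool_brew_times": self.pool_brew_times,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Recognized keys: out_dir, seed, n_iterations, infusion_csv,
    exposure (age group -> {DI, EF, ED, BW, rfd}), percentiles,
    pool_brew_times. Omitted exposure groups fall back to the defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FluoriskError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    exposure = default_exposure_blocks()
    for group, block in (raw.get("exposure") or {}).items():
        exposure.setdefault(group, {}).update(block)
    infusion_csv = raw.get("infusion_csv")
    if infusion_csv is not None:
        infusion_csv = Path(infusion_csv)
        if not infusion_csv.exists():
            raise FluoriskError(f"infusion CSV not found: {infusion_csv}")
    return RunConfig(
        out_dir=Path(raw.get("out_dir", "fluorisk_out")),
        seed=int(raw.get("seed", 0)),
        n_iterations=int(raw.get("n_iterations", 10_000)),
        infusion_csv=infusion_csv,
        exposure=exposure,
        percentiles=tuple(raw.get("percentiles", (5.0, 95.0))),
        pool_brew_times=bool(raw.get("pool_brew_times", True)),
    )


def fit_concentration_specs(
    dataset: InfusionDataset, pool_brew_times: bool = True
) -> dict[str, dist.DistributionSpec]:
    """Per product type, fit a triangular concentration distribution to the
    (optionally time-pooled) uncensored measurements."""
    specs: dict[str, dist.DistributionSpec] = {}
    types = sorted({r.product_type for r in dataset})
    for ptype in types:
        values = dataset.values(product_type=ptype)
        if pool_brew_times:
            specs[ptype] = dist.fit_triangular(values)
        else:
            # fit per time, then keep the 5-min spec (short brews are typical)
            specs[ptype] = dist.fit_triangular(
                dataset.values(product_type=ptype, brew_time_min=5.0)
            )
    return specs


def build_scenarios(
    c_specs: Mapping[str, dist.DistributionSpec],
    exposure: Mapping[str, Mapping[str, Any]],
) -> list[ExposureScenario]:
    """Cross product of fitted concentration specs and exposure blocks."""
    scenarios = []
    for age_group, block in exposure.items():
        for ptype, c_spec in c_specs.items():
            scenarios.append(
                ExposureScenario(
                    age_group=age_group,
                    product_type=ptype,
                    C=c_spec,
                    DI=dist.DistributionSpec.from_dict(block["DI"]),
                    EF=dist.DistributionSpec.from_dict(block["EF"]),
                    ED=dist.DistributionSpec.from_dict(block["ED"]),
                    BW=dist.DistributionSpec.from_dict(block["BW"]),
                    rfd=float(block["rfd"]),
                )
            )
    return scenarios


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"fluorisk {__version__}",
        f"seed={config.seed} n_iterations={config.n_iterations} config_sha={config.config_hash()}",
    ]


def _write_csv(df: pd.DataFrame, path: Path, provenance: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig, write_iterations: bool = True) -> dict[str, Any]:
    """Run the full analysis and write the report bundle to ``config.out_dir``.

    Outputs: ``infusion_data.csv``, ``group_summaries.csv``,
    ``pairwise_comparisons.csv``, ``fitted_concentrations.json``, per-scenario
    ``iterations_<type>_<group>.csv`` and ``summary_<type>_<group>.json``,
    ``sensitivity_<group>.csv``, the combined ``risk_table.csv`` and
    ``run_metadata.json``. Returns the bundle in memory (summaries keyed by
    (product_type, age_group), the combined table, sensitivity narratives).

    Outputs are staged in a temporary sibling directory and moved into place
    only on success, so a failing stage never leaves a half-written bundle.
    """
    out_dir = Path(config.out_dir)
    staging = out_dir.parent / (out_dir.name + ".partial")
    if staging.exists():
        for old in staging.iterdir():
            old.unlink()
    staging.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)

    logger.info("stage 1/5: dataset")
    if config.infusion_csv is not None:
        if not Path(config.infusion_csv).exists():
            raise FluoriskError(f"infusion CSV not found: {config.infusion_csv}")
        dataset = read_infusion_csv(config.infusion_csv)
    else:
        design = config.design or default_study_design(seed=config.seed)
        dataset = generate_infusion_study(design)
    write_infusion_csv(dataset, staging / "infusion_data.csv", prov)

    logger.info("stage 2/5: descriptive statistics")
    summaries = group_summaries(dataset, leaf_state=next(iter(dataset)).leaf_state)
    _write_csv(
        pd.DataFrame([s.__dict__ for s in summaries]),
        staging / "group_summaries.csv",
        prov,
    )
    comparisons = pairwise_type_comparisons(dataset, brew_time_min=5.0,
                                            leaf_state=next(iter(dataset)).leaf_state)
    _write_csv(comparisons, staging / "pairwise_comparisons.csv", prov)

    logger.info("stage 3/5: distribution fitting")
    c_specs = fit_concentration_specs(dataset, config.pool_brew_times)
    with open(staging / "fitted_concentrations.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"provenance": prov, "specs": {k: v.to_dict() for k, v in c_specs.items()}},
            fh,
            indent=2,
        )

    logger.info("stage 4/5: Monte Carlo simulation")
    scenarios = build_scenarios(c_specs, config.exposure)
    results = {}
    summaries_by_key = {}
    reports_by_group: dict[str, list] = {}
    for scenario in scenarios:
        result = run_monte_carlo(scenario, config.n_iterations, config.seed)
        key = (scenario.product_type, scenario.age_group)
        results[key] = result
        summary = summarize(result, cdi_reference=0.06)
        summaries_by_key[key] = summary
        stem = f"{scenario.product_type}_{scenario.age_group}"
        if write_iterations:
            _write_csv(result.to_frame(), staging / f"iterations_{stem}.csv", prov)
        with open(staging / f"summary_{stem}.json", "w", encoding="utf-8") as fh:
            payload = {"provenance": prov, "scenario": scenario.to_dict()}
            payload.update(summary.to_dict())
            json.dump(payload, fh, indent=2)
        reports_by_group.setdefault(scenario.age_group, []).append(
            contribution_to_variance(result, output="HQ")
        )

    logger.info("stage 5/5: sensitivity and combined table")
    narratives = {}
    for age_group, reports in reports_by_group.items():
        rows = []
        for rep in reports:
            frame = rep.to_frame()
            frame.insert(0, "scenario", rep.scenario_label)
            rows.append(frame)
        _write_csv(pd.concat(rows, ignore_index=True), staging / f"sensitivity_{age_group}.csv", prov)
        narratives[age_group] = sensitivity_narrative(reports)
        _write_csv(narratives[age_group], staging / f"sensitivity_ranges_{age_group}.csv", prov)

    table_rows = []
    for ptype in sorted({k[0] for k in summaries_by_key}):
        row: dict[str, Any] = {"product_type": ptype}
        for age_group in config.exposure:
            s = summaries_by_key[(ptype, age_group)]
            row[f"{age_group}_cdi_p5"] = s.cdi_p5
            row[f"{age_group}_cdi_mean"] = s.cdi_mean
            row[f"{age_group}_cdi_p95"] = s.cdi_p95
            row[f"{age_group}_hq_p5"] = s.hq_p5
            row[f"{age_group}_hq_mean"] = s.hq_mean
            row[f"{age_group}_hq_p95"] = s.hq_p95
            row[f"{age_group}_p_hq_gt_1"] = s.p_hq_above_1
        table_rows.append(row)
    risk_table = pd.DataFrame(table_rows)
    _write_csv(risk_table, staging / "risk_table.csv", prov)

    with open(staging / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "package_version": __version__,
                "seed": config.seed,
                "n_iterations": config.n_iterations,
                "config_sha": config.config_hash(),
                "scenarios": len(scenarios),
            },
            fh,
            indent=2,
        )

    # success: promote the staged bundle
    out_dir.mkdir(parents=True, exist_ok=True)
    for item in staging.iterdir():
        target = out_dir / item.name
        if target.exists():
            target.unlink()
        item.replace(target)
    staging.rmdir()

    return {
        "dataset": dataset,
        "group_summaries": summaries,
        "concentration_specs": c_specs,
        "results": results,
        "summaries": summaries_by_key,
        "risk_table": risk_table,
        "sensitivity_narratives": narratives,
        "out_dir": out_dir,
    }
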