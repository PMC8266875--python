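"""Contribution-to-variance sensitivity analysis.

Identifies which exposure input drives the simulated risk output, using the
signed, normalized squared rank correlation (the statistic behind the
tornado charts of commercial risk software):

    r_i            = Spearman rho between input i's draws and the output
    contribution_i = sign(r_i) * r_i^2 / sum_j r_j^2 * 100   [percent]

summed over the varying inputs j. Absolute contributions total 100%;
zero-variance (point-mass) inputs are excluded from the normalization and
reported with a contribution of exactly 0 and a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError
from .risk import INPUT_NAMES, RiskResult

__all__ = [
    "ParameterSensitivity",
    "SensitivityReport",
    "contribution_to_variance",
    "contribution_from_arrays",
    "sensitivity_narrative",
]


@dataclass(frozen=True)
class ParameterSensitivity:
    """One input's rank correlation and variance share."""

    name: str
    rho: float
    contribution_pct: float
    varies: bool


@dataclass(frozen=True)
class SensitivityReport:
    """Per-input contributions for one simulation, ordered by |contribution|."""

    output: str
    entries: tuple[ParameterSensitivity, ...]
    scenario_label: str = ""

    def contribution(self, name: str) -> float:
        for e in self.entries:
            if e.name == name:
                return e.contribution_pct
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": [e.name for e in self.entries],
                "rho": [e.rho for e in self.entries],
                "contribution_pct": [e.contribution_pct for e in self.entries],
                "varies": [e.varies for e in self.entries],
            }
        )


def contribution_from_arrays(
    inputs: dict[str, np.ndarray],
    output: np.ndarray,
    output_name: str = "output",
    scenario_label: str = "",
) -> SensitivityReport:
    """Contribution-to-variance over arbitrary aligned input/output arrays."""
    if output.size < 2:
        raise DegenerateInputError("need at least 2 iterations for a sensitivity analysis")
    varying = {k: v for k, v in inputs.items() if np.ptp(v) > 0}
    if not varying:
        raise DegenerateInputError("all inputs are constant; nothing to attribute variance to")
    if np.ptp(output) == 0:
        raise DegenerateInputError("output is constant; variance contributions are undefined")
    rho = {k: float(sps.spearmanr(v, output).statistic) for k, v in varying.items()}
    denom = sum(r * r for r in rho.values())
    entries = []
    for name, x in inputs.items():
        if name in rho:
            r = rho[name]
            contribution = float(np.sign(r) * r * r / denom * 100.0)
            entries.append(ParameterSensitivity(name, r, contribution, True))
        else:
            entries.append(ParameterSensitivity(name, 0.0, 0.0, False))
    entries.sort(key=lambda e: abs(e.contribution_pct), reverse=True)
    return SensitivityReport(output=output_name, entries=tuple(entries), scenario_label=scenario_label)


def contribution_to_variance(result: RiskResult, output: str = "HQ") -> SensitivityReport:
    """Contribution-to-variance of every exposure input to CDI or HQ.

    HQ is a fixed rescaling of CDI, so both outputs yield identical
    contributions; the choice only labels the report.
    """
    if output not in ("CDI", "HQ"):
        raise ValueError(f"output must be 'CDI' or 'HQ', got {output!r}")
    out = result.cdi if output == "CDI" else result.hq
    label = f"{result.scenario.product_type}/{result.scenario.age_group}"
    return contribution_from_arrays(
        {name: result.inputs[name] for name in INPUT_NAMES}, out, output, label
    )


def sensitivity_narrative(reports: Sequence[SensitivityReport]) -> pd.DataFrame:
    """Cross-scenario digest: per parameter, the range of signed contributions
    over all reports, as min/max columns plus a formatted "low%-high%" label,
    ordered by the largest absolute contribution seen anywhere."""
    if not reports:
        raise DegenerateInputError("need at least one sensitivity report")
    names: list[str] = []
    for rep in reports:
        for e in rep.entries:
            if e.name not in names:
                names.append(e.name)
    rows = []
    for name in names:
        vals = [rep.contribution(name) for rep in reports if any(e.name == name for e in rep.entries)]
        lo, hi = min(vals), max(vals)
        rows.append(
            {
                "parameter": name,
                "min_contribution_pct": lo,
                "max_contribution_pct": hi,
                "range": f"{lo:.1f}%–{hi:.1f}%",
                "max_abs_contribution_pct": max(abs(v) for v in vals),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "max_abs_contribution_pct", ascending=False, ignore_index=True
    )
    return table
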