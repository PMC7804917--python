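"""Configuration loading, validation, and the sensitivity-parameter registry.

The model is fully config-driven: clinical parameters, the cost schedule, the
adverse-event management table, and the background-mortality life table are
plain text files bundled with the package (``brafcea/data``) and replaceable
via paths.  Values with a deterministic range are stored as
``{base, low, high}`` nodes; scalar nodes are fixed.

``PARAM_REGISTRY`` enumerates every parameter eligible for sensitivity
analysis, with a stable id, its location in the nested config, and its kind
(cost / probability / utility / hazard ratio), which determines both the
one-way range and the probabilistic sampling family.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Params",
    "ParamRange",
    "SAParam",
    "PARAM_REGISTRY",
    "load_params",
    "base_value",
    "data_path",
]


class ConfigError(ValueError):
    """Malformed or incomplete configuration."""


def data_path(name: str) -> Path:
    """Path to a bundled data file."""
    return Path(str(resources.files("brafcea").joinpath("data", name)))


def base_value(node: Any) -> float:
    """Base-case value of a config node (dict-with-base or bare scalar)."""
    if isinstance(node, Mapping):
        return float(node["base"])
    return float(node)


@dataclass(frozen=True)
class ParamRange:
    """A parameter with its one-way sensitivity range; low <= base <= high."""

    param_id: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ConfigError(
                f"{self.param_id}: range ({self.low}, {self.high}) must contain "
                f"base {self.base}"
            )


@dataclass(frozen=True)
class SAParam:
    """Registry entry: where a sensitivity parameter lives and what it is."""

    param_id: str
    section: str  # "clinical" or "costs"
    path: tuple[str, ...]
    kind: str  # cost | probability | utility | hazard_ratio | rate | count | age


# Every parameter with a printed range enters one-way sensitivity analysis;
# kinds drive the probabilistic distributions (gamma for costs, beta for
# probabilities and utilities, log-normal for the hazard ratio).
PARAM_REGISTRY: tuple[SAParam, ...] = (
    SAParam("doublet_hr", "clinical", ("doublet_hr",), "hazard_ratio"),
    SAParam("discount_annual", "clinical", ("discount_annual",), "rate"),
    SAParam("pct_folfiri", "clinical", ("pct_folfiri",), "probability"),
    SAParam("ae_discontinue_standard", "clinical", ("ae_discontinue", "standard"), "probability"),
    SAParam("ae_discontinue_doublet", "clinical", ("ae_discontinue", "doublet"), "probability"),
    SAParam("ae_discontinue_regorafenib", "clinical", ("ae_discontinue", "regorafenib"), "probability"),
    SAParam("ae_discontinue_nivo_ipi", "clinical", ("ae_discontinue", "nivo_ipi"), "probability"),
    SAParam("ae_mortality_standard", "clinical", ("ae_mortality", "standard"), "probability"),
    SAParam("ae_mortality_doublet", "clinical", ("ae_mortality", "doublet"), "probability"),
    SAParam("ae_mortality_regorafenib", "clinical", ("ae_mortality", "regorafenib"), "probability"),
    SAParam("pct_msi_h", "clinical", ("pct_msi_h",), "probability"),
    SAParam("nivo_max_doses", "clinical", ("nivo_max_doses",), "count"),
    SAParam("start_age", "clinical", ("start_age",), "age"),
    SAParam("utility", "clinical", ("utility",), "utility"),
    SAParam("cost_encorafenib", "costs", ("drugs", "encorafenib"), "cost"),
    SAParam("cost_regorafenib", "costs", ("drugs", "regorafenib"), "cost"),
    SAParam("cost_cetuximab", "costs", ("drugs", "cetuximab"), "cost"),
    SAParam("cost_irinotecan", "costs", ("drugs", "irinotecan"), "cost"),
    SAParam("cost_fluorouracil", "costs", ("drugs", "fluorouracil"), "cost"),
    SAParam("cost_folinic_acid", "costs", ("drugs", "folinic_acid"), "cost"),
    SAParam("cost_nivolumab", "costs", ("drugs", "nivolumab"), "cost"),
    SAParam("cost_ipilimumab", "costs", ("drugs", "ipilimumab"), "cost"),
    SAParam("cost_office_visit", "costs", ("monitoring", "office_visit"), "cost"),
    SAParam("cost_cbc", "costs", ("monitoring", "cbc"), "cost"),
    SAParam("cost_cea", "costs", ("monitoring", "cea"), "cost"),
    SAParam("cost_alt", "costs", ("monitoring", "alt"), "cost"),
    SAParam("cost_ast", "costs", ("monitoring", "ast"), "cost"),
    SAParam("cost_lipase", "costs", ("monitoring", "lipase"), "cost"),
    SAParam("cost_infusion_first_hour", "costs", ("administration", "infusion_first_hour"), "cost"),
    SAParam("cost_infusion_additional_hour", "costs", ("administration", "infusion_additional_hour"), "cost"),
    SAParam("cost_infusion_additional_sequence", "costs", ("administration", "infusion_additional_sequence"), "cost"),
    SAParam("cost_preinfusion_medication", "costs", ("administration", "preinfusion_medication"), "cost"),
    SAParam("cost_ct_abdomen_pelvis", "costs", ("monitoring", "ct_abdomen_pelvis"), "cost"),
    SAParam("cost_end_of_life", "costs", ("end_of_life",), "cost"),
)

_REQUIRED_CLINICAL = (
    "survival", "doublet_hr", "discount_annual", "pct_folfiri", "ae_discontinue",
    "ae_mortality", "pct_msi_h", "nivo_max_doses", "ipi_max_doses", "start_age",
    "pct_male", "bsc_months", "os_target_months", "utility", "wtp_per_qaly",
    "horizon_cycles",
)
_REQUIRED_COSTS = ("drugs", "administration", "monitoring", "end_of_life", "dosing")


@dataclass(frozen=True)
class Params:
    """Full parameter set: clinical inputs, costs, AE table, life table."""

    clinical: dict
    costs: dict
    ae_costs: dict
    life_table: pd.DataFrame = field(repr=False)

    # -- accessors -----------------------------------------------------------

    def clin(self, *path: str) -> float:
        return base_value(_walk(self.clinical, path, "clinical"))

    def cost(self, *path: str) -> float:
        return base_value(_walk(self.costs, path, "costs"))

    @property
    def horizon(self) -> int:
        return int(self.clinical["horizon_cycles"])

    @property
    def discount(self) -> float:
        return self.clin("discount_annual")

    @property
    def utility(self) -> float:
        return self.clin("utility")

    @property
    def wtp(self) -> float:
        return float(self.clinical["wtp_per_qaly"])

    def node(self, section: str, path: tuple[str, ...]) -> Any:
        root = self.clinical if section == "clinical" else self.costs
        return _walk(root, path, section)

    def sa_range(self, sa: SAParam) -> ParamRange | None:
        """One-way range for a registry entry; None when no range is printed."""
        node = self.node(sa.section, sa.path)
        if not isinstance(node, Mapping) or "low" not in node or "high" not in node:
            return None
        return ParamRange(sa.param_id, float(node["base"]), float(node["low"]), float(node["high"]))

    # -- modification --------------------------------------------------------

    def with_overrides(self, overrides: Mapping[str, float]) -> "Params":
        """Copy with base values replaced; keys are registry param ids."""
        by_id = {sa.param_id: sa for sa in PARAM_REGISTRY}
        clinical = copy.deepcopy(self.clinical)
        costs = copy.deepcopy(self.costs)
        for pid, value in overrides.items():
            if pid == "bsc_months":  # calibrated scalar, not in the registry
                clinical["bsc_months"] = float(value)
                continue
            if pid not in by_id:
                raise ConfigError(f"unknown parameter id {pid!r}")
            sa = by_id[pid]
            root = clinical if sa.section == "clinical" else costs
            node = _walk(root, sa.path, sa.section)
            if isinstance(node, Mapping):
                node["base"] = float(value)
            else:
                parent = _walk(root, sa.path[:-1], sa.section)
                parent[sa.path[-1]] = float(value)
        return replace(self, clinical=clinical, costs=costs)

    def with_bsc_months(self, months: float) -> "Params":
        return self.with_overrides({"bsc_months": months})


def _walk(root: Mapping, path: Iterable[str], section: str) -> Any:
    node: Any = root
    for key in path:
        try:
            node = node[key]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"missing {section} config key {'.'.join(path)!r}") from exc
    return node


def _load_yaml(path: Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return out


def load_params(
    parameters: str | Path | None = None,
    costs: str | Path | None = None,
    ae_costs: str | Path | None = None,
    life_table: str | Path | None = None,
) -> Params:
    """Load the full parameter set, bundled defaults for any path not given."""
    clin = _load_yaml(Path(parameters) if parameters else data_path("parameters.yaml"))
    cost = _load_yaml(Path(costs) if costs else data_path("costs.yaml"))
    ae = _load_yaml(Path(ae_costs) if ae_costs else data_path("ae_costs.yaml"))
    lt = pd.read_csv(Path(life_table) if life_table else data_path("life_table.csv"),
                     comment="#")

    missing = [k for k in _REQUIRED_CLINICAL if k not in clin]
    missing += [f"costs.{k}" for k in _REQUIRED_COSTS if k not in cost]
    if missing:
        raise ConfigError(f"missing required config keys: {missing}")
    for col in ("age", "male", "female"):
        if col not in lt.columns:
            raise ConfigError(f"life table lacks column {col!r}")
    return Params(clinical=clin, costs=cost, ae_costs=ae, life_table=lt)
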