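"""Domain types for stochastic partial budgeting of livestock interventions.

A partial budget compares only the cash flows that change under an
intervention against the status quo.  Each changed cash flow is a
:class:`CashFlowItem` carrying a three-point (minimum, most-likely, maximum)
monetary estimate, interpreted as a triangular distribution; a
:class:`Scenario` bundles the items for one intervention.  All monetary
values are GBP per pig produced.

Scenarios are plain data and round-trip through a small YAML schema, so the
three packaged intervention fixtures and user-defined scenarios share one
code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "TriangularEstimate",
    "CashFlowItem",
    "Scenario",
    "SimConfig",
    "FIXTURE_IDS",
    "load_scenario_fixtures",
    "load_scenario_fixture",
    "validate_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "read_scenario",
    "write_scenario",
]

FIXTURE_IDS = ("socialisation", "large_groups", "pheromones")

DIRECTIONS = ("cost", "benefit")
SOURCES = ("farmer_survey", "literature", "market")


@dataclass(frozen=True)
class TriangularEstimate:
    """A (low, mode, high) monetary estimate defining a triangular distribution.

    The degenerate case ``low == mode == high`` is allowed and denotes a
    point mass.  Units are GBP per pig produced throughout the package.
    """

    low: float
    mode: float
    high: float

    def violations(self, context: str = "estimate") -> list[str]:
        out = []
        vals = (self.low, self.mode, self.high)
        if not all(math.isfinite(v) for v in vals):
            out.append(f"{context}: non-finite value in {vals}")
            return out
        if not (self.low <= self.mode <= self.high):
            out.append(
                f"{context}: ordering low <= mode <= high violated by "
                f"({self.low}, {self.mode}, {self.high})"
            )
        return out

    @property
    def is_degenerate(self) -> bool:
        return self.low == self.high

    @property
    def mean(self) -> float:
        """Theoretical mean (low + mode + high) / 3."""
        return (self.low + self.mode + self.high) / 3.0

    def scaled(self, k: float) -> "TriangularEstimate":
        return TriangularEstimate(self.low * k, self.mode * k, self.high * k)


@dataclass(frozen=True)
class CashFlowItem:
    """One named cost or benefit component of a partial budget.

    ``direction`` fixes the sign convention at simulation time: benefits
    enter the net effect positively, costs negatively.  ``source`` records
    where the estimate came from (farmer survey, literature or market
    information) and has no computational role.
    """

    name: str
    direction: str
    estimate: TriangularEstimate
    source: str = "farmer_survey"

    def violations(self) -> list[str]:
        out = []
        if not self.name:
            out.append("item with empty name")
        if self.direction not in DIRECTIONS:
            out.append(f"item {self.name!r}: direction {self.direction!r} not in {DIRECTIONS}")
        if self.source not in SOURCES:
            out.append(f"item {self.name!r}: source {self.source!r} not in {SOURCES}")
        out.extend(self.estimate.violations(context=f"item {self.name!r}"))
        return out


@dataclass(frozen=True)
class Scenario:
    """The full set of changed cash flows for one intervention."""

    id: str
    label: str
    items: tuple[CashFlowItem, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def costs(self) -> tuple[CashFlowItem, ...]:
        return tuple(i for i in self.items if i.direction == "cost")

    @property
    def benefits(self) -> tuple[CashFlowItem, ...]:
        return tuple(i for i in self.items if i.direction == "benefit")

    def support(self) -> tuple[float, float]:
        """Analytic net-effect support from interval arithmetic on the bounds."""
        lo = sum(b.estimate.low for b in self.benefits) - sum(c.estimate.high for c in self.costs)
        hi = sum(b.estimate.high for b in self.benefits) - sum(c.estimate.low for c in self.costs)
        return lo, hi

    def scaled(self, k: float) -> "Scenario":
        return replace(
            self,
            items=tuple(replace(i, estimate=i.estimate.scaled(k)) for i in self.items),
        )


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo run configuration.

    ``n_samples`` defaults to 500 draws.  ``aggregate_mode`` selects whether
    each item is sampled independently (``components``) or the summed
    per-direction bounds are sampled as a single triangular (``totals``).
    """

    n_samples: int = 500
    seed: int = 0
    aggregate_mode: str = "components"

    def violations(self) -> list[str]:
        out = []
        if self.n_samples < 1:
            out.append(f"n_samples must be >= 1, got {self.n_samples}")
        if self.aggregate_mode not in ("components", "totals"):
            out.append(f"aggregate_mode {self.aggregate_mode!r} not in ('components', 'totals')")
        return out


def validate_scenario(s: Scenario) -> list[str]:
    """Return a list of invariant violations; empty iff the scenario is valid.

    Validation never raises: malformed scenarios come back as messages that
    identify the offending item and bound.
    """
    out: list[str] = []
    if not s.id:
        out.append("scenario id is empty")
    if len(s.items) == 0:
        out.append(f"scenario {s.id!r}: has no items")
    names = [i.name for i in s.items]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        out.append(f"scenario {s.id!r}: duplicate item names {sorted(dupes)}")
    for item in s.items:
        out.extend(item.violations())
    return out


# ---------------------------------------------------------------------------
# Serialisation

def scenario_to_dict(s: Scenario) -> dict:
    return {
        "id": s.id,
        "label": s.label,
        "items": [
            {
                "name": i.name,
                "direction": i.direction,
                "source": i.source,
                "low": i.estimate.low,
                "mode": i.estimate.mode,
                "high": i.estimate.high,
            }
            for i in s.items
        ],
    }


def scenario_from_dict(d: dict) -> Scenario:
    try:
        items = tuple(
            CashFlowItem(
                name=str(it["name"]),
                direction=str(it["direction"]),
                source=str(it.get("source", "farmer_survey")),
                estimate=TriangularEstimate(
                    float(it["low"]), float(it["mode"]), float(it["high"])
                ),
            )
            for it in d.get("items", [])
        )
        return Scenario(id=str(d["id"]), label=str(d.get("label", d["id"])), items=items)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed scenario document: {exc}") from exc


def read_scenario(path: str | Path) -> Scenario:
    """Read one scenario from a YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return scenario_from_dict(doc)


def write_scenario(s: Scenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(s), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Packaged fixtures

def _fixture_dir():
    return resources.files("spbudget").joinpath("data", "scenarios")


def load_scenario_fixture(scenario_id: str) -> Scenario:
    """Load one of the packaged intervention scenarios by id."""
    if scenario_id not in FIXTURE_IDS:
        raise KeyError(f"unknown fixture {scenario_id!r}; expected one of {FIXTURE_IDS}")
    with resources.as_file(_fixture_dir().joinpath(f"{scenario_id}.yaml")) as p:
        return read_scenario(p)


def load_scenario_fixtures() -> list[Scenario]:
    """The three packaged intervention scenarios, in canonical order.

    Returns pre-weaning socialisation, large social groups (100+) and
    synthetic maternal pheromones, each carrying its published cost and
    benefit envelope in GBP per pig produced.
    """
    return [load_scenario_fixture(sid) for sid in FIXTURE_IDS]


def load_params(name: str) -> dict:
    """Load a packaged parameter fixture (``growth_penalty``,
    ``pheromone_dosing``, ``wtp_classes`` or ``conversion``)."""
    f = resources.files("spbudget").joinpath("data", "params", f"{name}.yaml")
    with resources.as_file(f) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)
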