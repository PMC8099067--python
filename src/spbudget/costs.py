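"""Cost and benefit sub-models feeding the packaged scenario envelopes.

Three families of inputs stand behind the intervention scenarios:

* a linear average-daily-gain (ADG) model monetising the growth penalty of
  housing growing pigs in larger groups;
* a diffuser dosing model for synthetic maternal pheromones (purchase and
  installation labour, per pig produced);
* simple scaling rules for survey-derived benefits and for amortising
  structural investments.

Where a sub-model's exact market inputs are not independently sourced, the
shipped parameter fixture is calibrated to reproduce the packaged scenario
rows and says so in its ``calibrated_to`` field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import TriangularEstimate, load_params

__all__ = [
    "GrowthModelParams",
    "PheromoneDosingParams",
    "adg",
    "growth_penalty_cost",
    "growth_penalty_fixture",
    "pheromone_cost_per_pig",
    "pheromone_fixture_params",
    "benefit_from_farmer_estimate",
    "cleaning_benefit_fixture",
    "amortise",
]


@dataclass(frozen=True)
class GrowthModelParams:
    """Linear ADG decline with group size, monetised over a growing phase.

    ADG for a growing pig is modelled as ``adg_intercept`` (kg/day) minus
    ``adg_slope_per_pig`` (kg/day) for each additional pig in the group.
    ``days_on_phase`` and ``price_per_kg`` convert a kg/day deficit into
    GBP per pig produced.
    """

    adg_intercept: float = 0.65
    adg_slope_per_pig: float = 0.00048
    days_on_phase: float = 83.3
    price_per_kg: float = 0.80

    def __post_init__(self):
        if self.adg_intercept <= 0:
            raise ValueError("adg_intercept must be positive")
        if self.adg_slope_per_pig < 0 or self.days_on_phase < 0 or self.price_per_kg < 0:
            raise ValueError("slope, days and price must be non-negative")


def adg(group_size: int, p: GrowthModelParams = GrowthModelParams()) -> float:
    """Average daily gain (kg/day) at the given group size, floored at zero."""
    if group_size < 0:
        raise ValueError("group_size must be >= 0")
    return max(0.0, p.adg_intercept - p.adg_slope_per_pig * group_size)


def growth_penalty_cost(base_group: int, target_group: int,
                        p: GrowthModelParams = GrowthModelParams()) -> float:
    """GBP per pig produced lost to slower growth when enlarging the group.

    (adg(base) - adg(target)) x days on phase x price per kg; zero when the
    group size is unchanged.  Linear in both days and price.
    """
    if target_group < base_group:
        raise ValueError("target_group must be >= base_group")
    return (adg(base_group, p) - adg(target_group, p)) * p.days_on_phase * p.price_per_kg


def growth_penalty_fixture() -> TriangularEstimate:
    """Growth-penalty envelope from the shipped calibrated parameters.

    Evaluates the penalty for the packaged 50 -> 100 pig group-size change
    at the low/central/high price-per-kg points of the fixture file.
    """
    d = load_params("growth_penalty")
    prices = d["price_per_kg"]
    vals = []
    for key in ("low", "central", "high"):
        p = GrowthModelParams(
            adg_intercept=d["adg_intercept"],
            adg_slope_per_pig=d["adg_slope_per_pig"],
            days_on_phase=d["days_on_phase"],
            price_per_kg=prices[key],
        )
        vals.append(growth_penalty_cost(d["base_group_size"], d["target_group_size"], p))
    return TriangularEstimate(*vals)


@dataclass(frozen=True)
class PheromoneDosingParams:
    """Diffuser dosing for synthetic maternal pheromones.

    Product instructions: one diffuser per ``area_per_diffuser`` m2 of pen,
    effective for ``diffuser_life_weeks`` weeks after opening (the 1.5 m
    mounting height has no monetary consequence and is not modelled).  One
    installation cycle serves the ``pigs_per_pen`` pigs housed on the
    covered area, so ``weeks_required`` may not exceed the diffuser life.
    """

    price_per_diffuser: float
    pen_area: float
    pigs_per_pen: int
    labour_minutes_per_diffuser: float
    wage_per_hour: float
    area_per_diffuser: float = 25.0
    diffuser_life_weeks: float = 6.0
    weeks_required: float = 6.0

    def __post_init__(self):
        if self.area_per_diffuser <= 0 or self.diffuser_life_weeks <= 0:
            raise ValueError("area_per_diffuser and diffuser_life_weeks must be positive")
        if self.weeks_required > self.diffuser_life_weeks:
            raise ValueError("weeks_required exceeds one diffuser lifetime")
        if self.pigs_per_pen <= 0:
            raise ValueError("a diffuser must serve at least one pig")


def diffusers_needed(p: PheromoneDosingParams) -> int:
    """Diffusers per pen under the one-per-25-m2 rule (ceiling)."""
    return math.ceil(p.pen_area / p.area_per_diffuser)


def pheromone_cost_per_pig(p: PheromoneDosingParams) -> tuple[float, float]:
    """(purchase, labour) cost in GBP per pig produced for one dosing cycle.

    Purchase: diffuser price x diffusers needed, spread over the pigs the
    diffusers serve during one lifetime.  Labour: installation minutes per
    diffuser at the given wage, spread over the same pigs.
    """
    n_diff = diffusers_needed(p)
    purchase = p.price_per_diffuser * n_diff / p.pigs_per_pen
    labour = (p.labour_minutes_per_diffuser * n_diff / 60.0) * p.wage_per_hour / p.pigs_per_pen
    return purchase, labour


def pheromone_fixture_params() -> dict[str, PheromoneDosingParams]:
    """Shipped calibrated dosing parameters at the low/central/high points."""
    d = load_params("pheromone_dosing")
    out = {}
    for key in ("low", "central", "high"):
        out[key] = PheromoneDosingParams(
            price_per_diffuser=d["price_per_diffuser"][key],
            pen_area=d["pen_area_m2"],
            pigs_per_pen=d["pigs_per_pen"],
            labour_minutes_per_diffuser=d["labour_minutes_per_diffuser"][key],
            wage_per_hour=d["wage_per_hour"],
            area_per_diffuser=d["area_per_diffuser_m2"],
            diffuser_life_weeks=d["diffuser_life_weeks"],
            weeks_required=d["weeks_required"],
        )
    return out


def benefit_from_farmer_estimate(max_saving: float) -> TriangularEstimate:
    """Triangular benefit envelope from the farmers' 50%-reduction estimate.

    Farmers priced the saving under an optimistic 50% reduction in
    aggression; that figure is the maximum.  The most likely value halves
    it, matching a more realistic 25% reduction under an assumed linear
    benefit-reduction relationship, and the minimum is no benefit at all.
    """
    if max_saving < 0:
        raise ValueError("max_saving must be >= 0")
    return TriangularEstimate(0.0, max_saving / 2.0, max_saving)


def cleaning_benefit_fixture() -> TriangularEstimate:
    """Reduced pen-cleaning labour in large groups (fewer gates/partitions)."""
    return TriangularEstimate(0.00, 0.01, 0.02)


def amortise(investment: float, lifetime_years: float, annual_output: float) -> float:
    """Linear, undiscounted amortisation of a structural investment.

    GBP per pig produced = investment / (lifetime x pigs produced per year).
    """
    if lifetime_years <= 0 or annual_output <= 0:
        raise ValueError("lifetime_years and annual_output must be positive")
    return investment / (lifetime_years * annual_output)
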