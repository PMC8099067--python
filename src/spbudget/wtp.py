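"""Willingness-to-pay conversion and viability classification.

A prior choice experiment identified three classes of pig farmers.  Only
the welfare-motivated class (half of respondents) pays for aggression
reduction specifically, at two rates per 1% reduction in aggression
lesions: an installation rate in GBP per pig place and a running rate in
GBP per pig produced.  A pig place houses successive pigs over its
lifetime, so the installation rate is spread over the pigs one place
produces before the installation wears out.

An intervention is *viable within WTP* when the worst simulated net cost
does not exceed what the class would pay for the assumed reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import SimulationResult
from .model import load_params

__all__ = [
    "WTPProfile",
    "wtp_per_pig",
    "classify_viability",
    "load_wtp_fixtures",
    "VERDICTS",
]

VERDICTS = ("profitable", "viable_within_wtp", "beyond_wtp")


@dataclass(frozen=True)
class WTPProfile:
    """One farmer class's willingness-to-pay rates per 1% lesion reduction."""

    class_label: str
    share_of_farmers: float
    install_rate: float  # GBP per pig place per 1% reduction
    running_rate: float  # GBP per pig produced per 1% reduction

    def __post_init__(self):
        if not (0.0 <= self.share_of_farmers <= 1.0):
            raise ValueError("share_of_farmers must lie in [0, 1]")
        if self.install_rate < 0 or self.running_rate < 0:
            raise ValueError("WTP rates must be non-negative")


def wtp_per_pig(p: WTPProfile, reduction_pct: float,
                pigs_per_place_lifetime: float) -> float:
    """Total WTP in GBP per pig produced for a given % lesion reduction.

    running_rate x reduction + install_rate x reduction spread over the
    pigs one place produces during the installation's lifetime.
    """
    if reduction_pct < 0:
        raise ValueError("reduction_pct must be >= 0")
    if pigs_per_place_lifetime <= 0:
        raise ValueError("pigs_per_place_lifetime must be positive")
    return (p.running_rate * reduction_pct
            + p.install_rate * reduction_pct / pigs_per_place_lifetime)


def worst_case_net_cost(r: SimulationResult, use_analytic_bound: bool = False,
                        analytic_lower: float | None = None) -> float:
    """Largest simulated net cost (GBP per pig produced); 0 if never negative.

    With ``use_analytic_bound`` the analytic support lower bound is used
    instead of the Monte Carlo sample minimum.
    """
    lower = analytic_lower if use_analytic_bound else r.sample_min
    if lower is None:
        raise ValueError("analytic_lower required when use_analytic_bound is set")
    return -lower if lower < 0 else 0.0


def classify_viability(r: SimulationResult, wtp_value: float,
                       use_analytic_bound: bool = False,
                       analytic_lower: float | None = None) -> str:
    """Classify an intervention against a WTP budget.

    ``profitable``: no simulated draw is a loss.  ``viable_within_wtp``:
    losses occur but even the worst one is covered by ``wtp_value``.
    ``beyond_wtp`` otherwise.  Increasing ``wtp_value`` never demotes a
    verdict.
    """
    if r.samples.size == 0:
        raise ValueError("empty simulation result")
    worst = worst_case_net_cost(r, use_analytic_bound, analytic_lower)
    if worst == 0.0:
        return "profitable"
    return "viable_within_wtp" if worst <= wtp_value else "beyond_wtp"


def load_wtp_fixtures() -> tuple[list[WTPProfile], float]:
    """Packaged farmer classes and the calibrated pigs-per-place lifetime."""
    d = load_params("wtp_classes")
    profiles = [
        WTPProfile(
            class_label=c["class_label"],
            share_of_farmers=float(c["share_of_farmers"]),
            install_rate=float(c["install_rate"]),
            running_rate=float(c["running_rate"]),
        )
        for c in d["classes"]
    ]
    return profiles, float(d["pigs_per_place_lifetime"])
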