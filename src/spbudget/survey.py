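"""Farmer-survey aggregation: heterogeneous cost answers to per-pig estimates.

Survey respondents report intervention costs on whatever scale comes
naturally — per pig, per pen or per whole farm — split into an initial
investment and an on-going (per batch / per year) component.  This module
converts every answer to GBP per pig produced, applies the inclusion rules
(complete cases only, blacklisted items dropped) and aggregates the
per-farmer totals into a (min, mean, max) envelope that the simulation
engine consumes as a triangular estimate.

Conversion conventions:

* ``per_pig`` answers pass through unchanged.
* ``per_pen`` answers are divided by the pigs a pen produces per year
  (pigs per pen x batches per year).
* ``per_farm`` answers are divided by the farm's annual output.
* investment answers are additionally amortised linearly over
  ``lifetime_years`` (default ten years).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TriangularEstimate, load_params

__all__ = [
    "FarmProfile",
    "SurveyEntry",
    "SurveyResponse",
    "ConversionParams",
    "AggregationResult",
    "to_per_pig",
    "aggregate",
    "aggregation_to_estimate",
    "responses_to_frames",
    "frames_to_responses",
    "read_survey",
    "write_survey",
    "DEFAULT_BLACKLIST",
]

SCALES = ("per_pig", "per_pen", "per_farm")
PHASES = ("investment", "ongoing")

# Mortality answers are excluded from aggregation: increased mortality under
# these interventions is not supported by the experimental literature.
DEFAULT_BLACKLIST = ("increased_mortality",)


@dataclass(frozen=True)
class ConversionParams:
    """Constants for re-expressing answers per pig produced."""

    lifetime_years: float = 10.0
    batches_per_year: float = 3.0
    pigs_per_sow_per_year: float = 25.0

    @classmethod
    def from_fixture(cls) -> "ConversionParams":
        d = load_params("conversion")
        return cls(
            lifetime_years=d["lifetime_years"],
            batches_per_year=d["batches_per_year"],
            pigs_per_sow_per_year=d["pigs_per_sow_per_year"],
        )


@dataclass(frozen=True)
class FarmProfile:
    """Herd structure of one respondent's farm."""

    sows: int = 0
    weaners: int = 0
    growers: int = 0
    finishers: int = 0
    pigs_per_pen: int = 0
    annual_output: float | None = None

    def output_per_year(self, conv: ConversionParams) -> float:
        """Pigs produced per year; derived from finisher places when not given."""
        if self.annual_output is not None and self.annual_output > 0:
            return float(self.annual_output)
        if self.finishers > 0:
            return self.finishers * conv.batches_per_year
        if self.sows > 0:
            return self.sows * conv.pigs_per_sow_per_year
        raise ValueError("annual output not derivable from profile")


@dataclass(frozen=True)
class SurveyEntry:
    """One cost answer: (scenario, item, phase) on a reporting scale."""

    scenario_id: str
    item_name: str
    phase: str  # investment | ongoing
    scale: str | None = None  # per_pig | per_pen | per_farm
    value: float | None = None
    answered: bool = True


@dataclass(frozen=True)
class SurveyResponse:
    """One farmer's profile and cost-item answers."""

    farmer_id: str
    profile: FarmProfile
    entries: tuple[SurveyEntry, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))


@dataclass(frozen=True)
class AggregationResult:
    """Min/mean/max per-pig totals across included farmers (one phase or total)."""

    scenario_id: str
    phase: str  # investment | ongoing | total
    low: float
    mean: float
    high: float
    std: float
    n_included: int
    excluded_items: tuple[str, ...] = ()

    @property
    def is_empty(self) -> bool:
        return self.n_included == 0


def to_per_pig(entry: SurveyEntry, profile: FarmProfile,
               conv: ConversionParams = ConversionParams()) -> float:
    """Convert one answered entry to GBP per pig produced.

    Raises ``ValueError`` when the profile lacks the fields the entry's
    scale needs (callers report this per entry and skip it).
    """
    if not entry.answered or entry.value is None:
        raise ValueError(f"entry {entry.item_name!r} is unanswered")
    if entry.value < 0:
        raise ValueError(f"entry {entry.item_name!r} has negative value {entry.value}")
    if entry.scale not in SCALES:
        raise ValueError(f"entry {entry.item_name!r} has unknown scale {entry.scale!r}")
    if entry.phase not in PHASES:
        raise ValueError(f"entry {entry.item_name!r} has unknown phase {entry.phase!r}")

    amortised = 1.0 / conv.lifetime_years if entry.phase == "investment" else 1.0
    if entry.scale == "per_pig":
        # already on the target scale (a per-pig investment answer is read
        # as already spread over the pigs the investment will serve)
        return entry.value
    if entry.scale == "per_pen":
        if profile.pigs_per_pen <= 0:
            raise ValueError("per_pen answer but pigs_per_pen missing from profile")
        pigs_per_pen_year = profile.pigs_per_pen * conv.batches_per_year
        return entry.value * amortised / pigs_per_pen_year
    # per_farm
    return entry.value * amortised / profile.output_per_year(conv)


def _farmer_totals(resp: SurveyResponse, scenario_id: str, blacklist: tuple[str, ...],
                   conv: ConversionParams, phase: str | None) -> float | None:
    """Per-pig total for one farmer, or None when the complete-case rule
    excludes them (an unanswered entry, no entries, or an unconvertible one)."""
    entries = [e for e in resp.entries
               if e.scenario_id == scenario_id and e.item_name not in blacklist]
    if not entries:
        return None
    if any(not e.answered for e in entries):
        return None  # must fully answer investment AND ongoing questions
    if phase is not None:
        entries = [e for e in entries if e.phase == phase]
    try:
        return sum(to_per_pig(e, resp.profile, conv) for e in entries)
    except ValueError:
        return None


def aggregate(responses: list[SurveyResponse], scenario_id: str,
              blacklist: tuple[str, ...] = DEFAULT_BLACKLIST,
              conv: ConversionParams = ConversionParams(),
              phase: str | None = None) -> AggregationResult:
    """Aggregate per-farmer totals into a (min, mean, max) envelope.

    A farmer contributes only if every non-blacklisted entry for the
    scenario — both investment and on-going — is answered (zero is an
    answer, not missingness).  ``phase`` restricts the summed entries to
    one phase while keeping the completeness rule on both.  An empty
    result (``n_included == 0``) is returned rather than raising.
    """
    if not responses:
        raise ValueError("at least one response required")
    totals = []
    for resp in responses:
        t = _farmer_totals(resp, scenario_id, tuple(blacklist), conv, phase)
        if t is not None:
            totals.append(t)
    phase_label = phase or "total"
    if not totals:
        return AggregationResult(scenario_id, phase_label, np.nan, np.nan, np.nan,
                                 np.nan, 0, tuple(blacklist))
    arr = np.asarray(totals)
    return AggregationResult(
        scenario_id=scenario_id,
        phase=phase_label,
        low=float(arr.min()),
        mean=float(arr.mean()),
        high=float(arr.max()),
        std=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n_included=int(arr.size),
        excluded_items=tuple(blacklist),
    )


def aggregation_to_estimate(a: AggregationResult) -> TriangularEstimate:
    """Survey envelope as a triangular estimate: the mean becomes the mode."""
    if a.is_empty:
        raise ValueError(f"no farmers included for {a.scenario_id!r}; cannot form an estimate")
    return TriangularEstimate(a.low, a.mean, a.high)


# ---------------------------------------------------------------------------
# Delimited-text I/O: one row per (farmer, scenario, item, phase) plus a
# farm-profile table keyed by farmer_id.

ENTRY_COLUMNS = ["farmer_id", "scenario_id", "item_name", "phase", "scale", "value", "answered"]
PROFILE_COLUMNS = ["farmer_id", "sows", "weaners", "growers", "finishers",
                   "pigs_per_pen", "annual_output"]


def responses_to_frames(responses: list[SurveyResponse]) -> tuple[pd.DataFrame, pd.DataFrame]:
    entry_rows, profile_rows = [], []
    for r in responses:
        p = r.profile
        profile_rows.append({
            "farmer_id": r.farmer_id, "sows": p.sows, "weaners": p.weaners,
            "growers": p.growers, "finishers": p.finishers,
            "pigs_per_pen": p.pigs_per_pen,
            "annual_output": p.annual_output if p.annual_output is not None else np.nan,
        })
        for e in r.entries:
            entry_rows.append({
                "farmer_id": r.farmer_id, "scenario_id": e.scenario_id,
                "item_name": e.item_name, "phase": e.phase,
                "scale": e.scale if e.answered else "",
                "value": e.value if e.answered else np.nan,
                "answered": e.answered,
            })
    return (pd.DataFrame(entry_rows, columns=ENTRY_COLUMNS),
            pd.DataFrame(profile_rows, columns=PROFILE_COLUMNS))


def frames_to_responses(entries: pd.DataFrame, profiles: pd.DataFrame) -> list[SurveyResponse]:
    for col in ENTRY_COLUMNS:
        if col not in entries.columns:
            raise ValueError(f"survey entries missing column {col!r}")
    for col in PROFILE_COLUMNS:
        if col not in profiles.columns:
            raise ValueError(f"farm profiles missing column {col!r}")
    out = []
    by_farmer = {str(row.farmer_id): row for row in profiles.itertuples()}
    grouped = entries.groupby("farmer_id", sort=False)
    for farmer_id, grp in grouped:
        farmer_id = str(farmer_id)
        if farmer_id not in by_farmer:
            raise ValueError(f"no farm profile for farmer {farmer_id!r}")
        prow = by_farmer[farmer_id]
        profile = FarmProfile(
            sows=int(prow.sows), weaners=int(prow.weaners), growers=int(prow.growers),
            finishers=int(prow.finishers), pigs_per_pen=int(prow.pigs_per_pen),
            annual_output=None if pd.isna(prow.annual_output) else float(prow.annual_output),
        )
        es = []
        for row in grp.itertuples():
            answered = bool(row.answered)
            es.append(SurveyEntry(
                scenario_id=str(row.scenario_id), item_name=str(row.item_name),
                phase=str(row.phase),
                scale=str(row.scale) if answered else None,
                value=float(row.value) if answered else None,
                answered=answered,
            ))
        out.append(SurveyResponse(farmer_id=farmer_id, profile=profile, entries=tuple(es)))
    return out


def write_survey(responses: list[SurveyResponse], entries_path: str | Path,
                 profiles_path: str | Path) -> None:
    entries, profiles = responses_to_frames(responses)
    entries.to_csv(entries_path, index=False)
    profiles.to_csv(profiles_path, index=False)


def read_survey(entries_path: str | Path, profiles_path: str | Path) -> list[SurveyResponse]:
    entries = pd.read_csv(entries_path)
    profiles = pd.read_csv(profiles_path)
    return frames_to_responses(entries, profiles)
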