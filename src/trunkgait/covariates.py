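"""Participant covariates: IPAQ physical-activity scoring and handheld
dynamometry hip-strength aggregation.

IPAQ (long form) converts self-reported frequency and duration of vigorous,
moderate and walking activity across four life domains into metabolic
equivalent task minutes per week (MET-min/week) and a low/moderate/high
category.  Hip strength is the per-muscle-group maximum of two maximal
trials per side, summarised as the bilateral mean (MS_average) and the
absolute between-limb difference (MS_diff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np

logger = logging.getLogger(__name__)

DOMAINS = ("work", "transport", "household", "leisure")
INTENSITIES = ("vigorous", "moderate", "walking")

#: MET coefficients per intensity (MET-min/week = coeff * days * minutes).
MET_COEFFICIENTS = {"vigorous": 8.0, "moderate": 4.0, "walking": 3.3}

#: Standard IPAQ cleaning: daily totals above 960 min are implausible and
#: truncated; bouts shorter than 10 min do not count.
MAX_MINUTES_PER_DAY = 960.0
MIN_BOUT_MINUTES = 10.0

MUSCLE_GROUPS = (
    "abductors",
    "adductors",
    "extensors",
    "flexors",
    "internal_rotators",
    "external_rotators",
)


@dataclass
class IpaqResponse:
    """Days/week and minutes/day per domain x intensity.

    Keys of ``days`` and ``minutes`` are ``(domain, intensity)`` tuples;
    unreported combinations default to zero.
    """

    days: dict = field(default_factory=dict)
    minutes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (dom, inten), d in self.days.items():
            if dom not in DOMAINS or inten not in INTENSITIES:
                raise ValueError(f"unknown domain/intensity {(dom, inten)}")
            if not (0 <= d <= 7) or d != int(d):
                raise ValueError(f"days must be an integer in [0, 7], got {d}")
        for key, m in self.minutes.items():
            if m < 0:
                raise ValueError(f"minutes must be >= 0, got {m} for {key}")


@dataclass
class IpaqScore:
    met_total: float
    met_by_intensity: dict
    category: str
    flags: list[str] = field(default_factory=list)


def score_ipaq(response: IpaqResponse) -> IpaqScore:
    """Score an IPAQ long-form response into MET-min/week and a category.

    Per intensity: MET-min/week = coefficient x days x minutes, summed over
    domains (8.0 vigorous, 4.0 moderate, 3.3 walking).  Minutes above
    960/day are truncated with a log entry; bouts under 10 min score zero.
    """
    flags: list[str] = []
    met_by_intensity = {i: 0.0 for i in INTENSITIES}
    days_by_intensity = {i: 0 for i in INTENSITIES}

    for dom in DOMAINS:
        for inten in INTENSITIES:
            d = response.days.get((dom, inten), 0)
            m = response.minutes.get((dom, inten), 0.0)
            if m > MAX_MINUTES_PER_DAY:
                flags.append(f"implausible_minutes:{dom}/{inten}={m}")
                logger.warning("IPAQ %s/%s minutes %s truncated to %s", dom, inten, m, MAX_MINUTES_PER_DAY)
                m = MAX_MINUTES_PER_DAY
            if m < MIN_BOUT_MINUTES:
                m = 0.0
            met_by_intensity[inten] += MET_COEFFICIENTS[inten] * d * m
            if d > 0 and m > 0:
                days_by_intensity[inten] = max(days_by_intensity[inten], d)

    met_total = float(sum(met_by_intensity.values()))
    category = _ipaq_category(response, met_by_intensity, met_total)
    return IpaqScore(
        met_total=met_total,
        met_by_intensity=met_by_intensity,
        category=category,
        flags=flags,
    )


def _active_days(response: IpaqResponse, intensities) -> int:
    """Largest reported active days/week over the given intensities."""
    best = 0
    for (dom, inten), d in response.days.items():
        m = response.minutes.get((dom, inten), 0.0)
        if inten in intensities and d > 0 and m >= MIN_BOUT_MINUTES:
            best = max(best, int(d))
    return best


def _total_days(response: IpaqResponse) -> int:
    """Days/week with any activity, summing across intensities (capped at 7)."""
    per_intensity = [_active_days(response, (i,)) for i in INTENSITIES]
    return min(7, sum(per_intensity))


def _ipaq_category(response: IpaqResponse, met_by_intensity: dict, met_total: float) -> str:
    """Official long-form category rules.

    high: vigorous on >= 3 days and total >= 1500 MET-min/week, OR any
    combination on >= 7 days and total >= 3000.
    moderate: vigorous >= 20 min/day on >= 3 days, OR moderate or walking
    >= 30 min/day on >= 5 days, OR any combination on >= 5 days reaching
    >= 600 MET-min/week.
    else low.
    """
    vig_days = _active_days(response, ("vigorous",))
    any_days = _total_days(response)
    if (vig_days >= 3 and met_total >= 1500) or (any_days >= 7 and met_total >= 3000):
        return "high"

    vig20 = any(
        response.days.get((dom, "vigorous"), 0) >= 3
        and response.minutes.get((dom, "vigorous"), 0.0) >= 20
        for dom in DOMAINS
    )
    modwalk30 = any(
        response.days.get((dom, inten), 0) >= 5
        and response.minutes.get((dom, inten), 0.0) >= 30
        for dom in DOMAINS
        for inten in ("moderate", "walking")
    )
    if vig20 or modwalk30 or (any_days >= 5 and met_total >= 600):
        return "moderate"
    return "low"


@dataclass
class StrengthRecord:
    """Aggregated strength for one muscle group (forces in newtons)."""

    muscle_group: str
    max_L: float | None
    max_R: float | None
    ms_average: float | None
    ms_diff: float | None
    flags: list[str] = field(default_factory=list)


def aggregate_strength(
    muscle_group: str,
    trials_L: tuple[float, float] | None,
    trials_R: tuple[float, float] | None,
) -> StrengthRecord:
    """Aggregate two maximal trials per side into the per-group summaries.

    The highest of the two trials per side is retained; MS_average is the
    mean of the two side maxima and MS_diff their absolute difference.
    A missing side leaves the bilateral summaries missing-flagged while the
    present side's maximum is kept.
    """
    if muscle_group not in MUSCLE_GROUPS:
        raise ValueError(f"unknown muscle group {muscle_group!r}")

    def side_max(trials, label):
        if trials is None:
            return None
        if len(trials) != 2:
            raise ValueError(f"{label}: exactly 2 trials required, got {len(trials)}")
        if any(t < 0 for t in trials):
            raise ValueError(f"{label}: negative force")
        return float(max(trials))

    max_L = side_max(trials_L, f"{muscle_group}/L")
    max_R = side_max(trials_R, f"{muscle_group}/R")
    flags: list[str] = []
    if max_L is None or max_R is None:
        flags.append("missing_side")
        ms_average = ms_diff = None
    else:
        ms_average = (max_L + max_R) / 2.0
        ms_diff = abs(max_L - max_R)
    return StrengthRecord(
        muscle_group=muscle_group,
        max_L=max_L,
        max_R=max_R,
        ms_average=ms_average,
        ms_diff=ms_diff,
        flags=flags,
    )
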