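"""Shared fixtures: hand-constructed archetype series and small cohorts."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from vcdkit.types import CstLabel, ParticipantSeries, SampleRecord

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: Bleeding days implied by a 28-day cycle with menses on days 1-5,
#: observed over cycle days 4-32.
BLEEDING_DAYS = frozenset({4, 5, 29, 30, 31, 32})


def make_series(
    participant_id,
    cst_for_day,
    day_range=(4, 32),
    bleeding_days=BLEEDING_DAYS,
    missing_days=frozenset(),
    intercourse_days=frozenset(),
):
    """Build a series from a day -> CST-token mapping function."""
    lo, hi = day_range
    records = []
    for day in range(lo, hi + 1):
        bleeding = day in bleeding_days
        intercourse = day in intercourse_days
        if day in missing_days:
            records.append(
                SampleRecord(
                    participant_id=participant_id,
                    cycle_day=day,
                    bleeding=bleeding,
                    intercourse=intercourse,
                    present=False,
                )
            )
        else:
            records.append(
                SampleRecord(
                    participant_id=participant_id,
                    cycle_day=day,
                    cst=CstLabel.parse(cst_for_day(day)),
                    bleeding=bleeding,
                    intercourse=intercourse,
                    present=True,
                    sample_id=f"{participant_id}_d{day:02d}",
                )
            )
    return ParticipantSeries(participant_id, tuple(records), day_range)


def archetype_series(kind: str, participant_id: str) -> ParticipantSeries:
    """Deterministic series exemplifying each dynamics category.

    constant archetypes are uniform; the menses-related archetype is
    dysbiotic on bleeding days plus one post-menses shoulder day
    (recovery lags bleeding by a day); the unstable archetype carries
    dysbiosis unrelated to menses (eubiotic during bleeding, dysbiotic
    mid-cycle except one day).
    """
    if kind == "constant_eubiotic":
        return make_series(participant_id, lambda d: "I-A")
    if kind == "constant_dysbiotic":
        return make_series(participant_id, lambda d: "IV-B")
    if kind == "menses_related_dysbiotic":
        return make_series(
            participant_id,
            lambda d: "IV-B" if (d in BLEEDING_DAYS or d == 6) else "I-A",
        )
    if kind == "unstable":
        return make_series(
            participant_id,
            lambda d: "I-A" if (d in BLEEDING_DAYS or d == 17) else "IV-B",
        )
    raise ValueError(kind)


ARCHETYPES = (
    "constant_eubiotic",
    "menses_related_dysbiotic",
    "unstable",
    "constant_dysbiotic",
)


@pytest.fixture(scope="session")
def archetype_cohort():
    return [archetype_series(kind, f"A_{kind}") for kind in ARCHETYPES]
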