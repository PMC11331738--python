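"""The vaginal community dynamics (VCD) decision tree.

A participant's daily CST series over one menstrual cycle is reduced to
one of four dynamics: constant eubiotic, constant dysbiotic,
menses-related dysbiotic, or unstable. The tree works on the fraction of
eubiotic samples, first over the whole series and, for intermediate
series, over a menses-free mid-cycle window (default cycle days 9-25).
Fractions are compared as exact rationals so the 80% boundaries are
reproducible.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Iterable, Optional, Tuple

import pandas as pd

from .types import (
    Branch,
    CstLabel,
    ParticipantSeries,
    VcdConfig,
    VcdDiagnostics,
    VcdLabel,
)

__all__ = [
    "is_eubiotic",
    "eubiotic_fraction",
    "classify_series",
    "classify_cohort",
    "EmptyDenominatorError",
]

logger = logging.getLogger(__name__)


class EmptyDenominatorError(ValueError):
    """No present samples inside the requested day filter."""


def is_eubiotic(cst: CstLabel, config: Optional[VcdConfig] = None) -> bool:
    """True iff the CST's main type belongs to the configured eubiotic set."""
    config = config or VcdConfig()
    return cst.main in config.eubiotic_csts


def eubiotic_fraction(
    series: ParticipantSeries,
    day_filter: Optional[Tuple[int, int]] = None,
    config: Optional[VcdConfig] = None,
) -> Tuple[int, int, Fraction]:
    """Count present and eubiotic samples, optionally inside a day window.

    Returns ``(n_present, n_eubiotic, fraction)``. Absent days are excluded
    from both numerator and denominator. Raises
    :class:`EmptyDenominatorError` when no present sample falls inside the
    filter.
    """
    config = config or VcdConfig()
    records = (
        series.in_window(day_filter) if day_filter is not None else series.present_records
    )
    n_present = len(records)
    if n_present == 0:
        raise EmptyDenominatorError(
            f"no present samples for {series.participant_id} in filter {day_filter}"
        )
    n_eub = sum(1 for r in records if is_eubiotic(r.cst, config))
    return n_present, n_eub, Fraction(n_eub, n_present)


def _passes(frac: Fraction, threshold: Fraction, inclusive: bool) -> bool:
    return frac >= threshold if inclusive else frac > threshold


def classify_series(
    series: ParticipantSeries, config: Optional[VcdConfig] = None
) -> Tuple[VcdLabel, VcdDiagnostics]:
    """Assign one VCD label to a participant series.

    Branch order: (1) enough eubiotic samples overall -> constant
    eubiotic; (2) enough dysbiotic samples overall -> constant dysbiotic;
    (3) otherwise decide on the mid-cycle window: mostly eubiotic there ->
    menses-related dysbiotic, else unstable. Series failing the
    sample-count guards are indeterminate rather than guessed.
    """
    config = config or VcdConfig()
    present = series.present_records
    n_present = len(present)
    n_eub = sum(1 for r in present if is_eubiotic(r.cst, config))

    mid = series.in_window(config.midcycle_window)
    n_mid = len(mid)
    n_mid_eub = sum(1 for r in mid if is_eubiotic(r.cst, config))

    if n_present < config.min_samples_total:
        diag = VcdDiagnostics(
            n_present=n_present,
            n_eubiotic=n_eub,
            frac_eubiotic_total=Fraction(n_eub, n_present) if n_present else None,
            n_midcycle_present=n_mid,
            n_midcycle_eubiotic=n_mid_eub,
            frac_eubiotic_midcycle=Fraction(n_mid_eub, n_mid) if n_mid else None,
            branch_taken=Branch.INSUFFICIENT,
        )
        return VcdLabel.INDETERMINATE, diag

    frac_total = Fraction(n_eub, n_present)
    frac_dys = 1 - frac_total
    frac_mid = Fraction(n_mid_eub, n_mid) if n_mid else None

    if _passes(frac_total, config.constant_eubiotic_min_frac, config.constant_eubiotic_inclusive):
        label, branch = VcdLabel.CONSTANT_EUBIOTIC, Branch.TOP_EUBIOTIC
    elif _passes(frac_dys, config.constant_dysbiotic_min_frac, config.constant_dysbiotic_inclusive):
        label, branch = VcdLabel.CONSTANT_DYSBIOTIC, Branch.TOP_DYSBIOTIC
    elif n_mid < config.min_samples_midcycle:
        label, branch = VcdLabel.INDETERMINATE, Branch.INSUFFICIENT
    elif _passes(frac_mid, config.midcycle_eubiotic_min_frac, config.midcycle_eubiotic_inclusive):
        label, branch = VcdLabel.MENSES_RELATED, Branch.MID_EUBIOTIC
    else:
        label, branch = VcdLabel.UNSTABLE, Branch.MID_OTHER

    diag = VcdDiagnostics(
        n_present=n_present,
        n_eubiotic=n_eub,
        frac_eubiotic_total=frac_total,
        n_midcycle_present=n_mid,
        n_midcycle_eubiotic=n_mid_eub,
        frac_eubiotic_midcycle=frac_mid,
        branch_taken=branch,
    )
    return label, diag


def classify_cohort(
    series_list: Iterable[ParticipantSeries], config: Optional[VcdConfig] = None
) -> pd.DataFrame:
    """Classify every participant; returns a deterministic per-row table.

    Columns: participant_id, vcd, n_samples, eubiotic_frac_total,
    n_midcycle, eubiotic_frac_midcycle, branch. Rows are sorted by
    participant id; per-label counts are emitted to the module logger.
    """
    config = config or VcdConfig()
    series_list = list(series_list)
    if not series_list:
        raise ValueError("empty cohort: nothing to classify")
    rows = []
    for series in sorted(series_list, key=lambda s: s.participant_id):
        label, diag = classify_series(series, config)
        rows.append(
            {
                "participant_id": series.participant_id,
                "vcd": label.value,
                "n_samples": diag.n_present,
                "eubiotic_frac_total": (
                    float(diag.frac_eubiotic_total)
                    if diag.frac_eubiotic_total is not None
                    else float("nan")
                ),
                "n_midcycle": diag.n_midcycle_present,
                "eubiotic_frac_midcycle": (
                    float(diag.frac_eubiotic_midcycle)
                    if diag.frac_eubiotic_midcycle is not None
                    else float("nan")
                ),
                "branch": diag.branch_taken.value,
            }
        )
    table = pd.DataFrame(rows)
    counts = table["vcd"].value_counts().to_dict()
    logger.info("VCD cohort counts: %s", counts)
    return table
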