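"""How few samples suffice to recover the full-series dynamics label.

Reduced designs are expressed as :class:`SubsampleScheme` objects: take
``n_menses`` samples from bleeding days and ``n_nonmenses`` from
menses-free days (by default restricted to the mid-cycle window, matching
the clinical reading of "samples outside menses"). Reference labels come
from the full series under the standard guards; subsampled series are
classified with guards relaxed to one sample so that tiny designs can be
scored at all.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import zlib
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classifier import classify_series
from .types import ParticipantSeries, VcdConfig, VcdLabel

__all__ = [
    "SubsampleScheme",
    "AgreementReport",
    "InfeasibleSchemeError",
    "subsample_series",
    "every_kth_day_scheme",
    "agreement_rate",
    "scheme_frontier",
]

logger = logging.getLogger(__name__)

#: Exhaustive enumeration is used when a series has at most this many
#: distinct selections; above it, random replicates are drawn instead.
EXHAUSTIVE_CAP = 5000


class InfeasibleSchemeError(ValueError):
    """The series lacks enough bleeding or menses-free days for the scheme."""


@dataclasses.dataclass(frozen=True)
class SubsampleScheme:
    """A constrained reduced-sampling design.

    ``n_menses``/``n_nonmenses`` of ``None`` mean "keep all available",
    so ``SubsampleScheme.identity()`` reproduces the full series.
    ``selection`` is ``"auto"`` (exhaustive when the combination count is
    at most ``exhaustive_cap``, random otherwise), ``"exhaustive"``,
    ``"random"`` or ``"systematic"`` (every ``stride`` days).
    """

    n_menses: Optional[int] = None
    n_nonmenses: Optional[int] = None
    selection: str = "auto"
    stride: Optional[int] = None
    n_reps: int = 200
    seed: int = 0
    midcycle_only: bool = True
    exhaustive_cap: int = EXHAUSTIVE_CAP

    def __post_init__(self) -> None:
        if self.selection not in ("auto", "exhaustive", "random", "systematic"):
            raise ValueError(f"unknown selection mode {self.selection!r}")
        for n in (self.n_menses, self.n_nonmenses):
            if n is not None and n < 0:
                raise ValueError("sample counts must be >= 0")
        if self.selection == "systematic" and (self.stride is None or self.stride < 1):
            raise ValueError("systematic selection requires stride >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @classmethod
    def identity(cls) -> "SubsampleScheme":
        return cls(n_menses=None, n_nonmenses=None, midcycle_only=False)

    @property
    def is_identity(self) -> bool:
        return self.n_menses is None and self.n_nonmenses is None and self.selection != "systematic"


def _pools(
    series: ParticipantSeries, scheme: SubsampleScheme, window: Tuple[int, int]
) -> Tuple[List[int], List[int]]:
    menses = [r.cycle_day for r in series.present_records if r.bleeding]
    if scheme.midcycle_only:
        lo, hi = window
        nonmenses = [
            r.cycle_day
            for r in series.present_records
            if not r.bleeding and lo <= r.cycle_day <= hi
        ]
    else:
        nonmenses = [r.cycle_day for r in series.present_records if not r.bleeding]
    return menses, nonmenses


def _n_combinations(scheme: SubsampleScheme, menses: Sequence[int], nonmenses: Sequence[int]) -> int:
    m = len(menses) if scheme.n_menses is None else scheme.n_menses
    k = len(nonmenses) if scheme.n_nonmenses is None else scheme.n_nonmenses
    return math.comb(len(menses), m) * math.comb(len(nonmenses), k)


def _rng_for(scheme: SubsampleScheme, participant_id: str, rep_index: int) -> np.random.Generator:
    pid_hash = zlib.crc32(participant_id.encode())
    return np.random.default_rng([scheme.seed, pid_hash, rep_index])


def iter_selections(
    series: ParticipantSeries,
    scheme: SubsampleScheme,
    window: Tuple[int, int],
) -> Iterator[Tuple[int, ...]]:
    """Yield the kept-day tuples for every replicate of a scheme."""
    if scheme.selection == "systematic":
        for offset in range(scheme.stride):
            kept = [
                r.cycle_day
                for r in series.present_records
                if r.cycle_day % scheme.stride == offset % scheme.stride
            ]
            if kept:
                yield tuple(kept)
        return

    menses, nonmenses = _pools(series, scheme, window)
    m = len(menses) if scheme.n_menses is None else scheme.n_menses
    k = len(nonmenses) if scheme.n_nonmenses is None else scheme.n_nonmenses
    if m + k == 0:
        raise InfeasibleSchemeError("scheme selects no samples")
    if len(menses) < m or len(nonmenses) < k:
        raise InfeasibleSchemeError(
            f"{series.participant_id}: needs {m} menses / {k} menses-free days, "
            f"has {len(menses)} / {len(nonmenses)}"
        )

    n_comb = _n_combinations(scheme, menses, nonmenses)
    exhaustive = scheme.selection == "exhaustive" or (
        scheme.selection == "auto" and n_comb <= scheme.exhaustive_cap
    )
    if scheme.selection == "exhaustive" and n_comb > scheme.exhaustive_cap:
        raise InfeasibleSchemeError(
            f"{n_comb} combinations exceed the exhaustive cap {scheme.exhaustive_cap}"
        )
    if exhaustive:
        for mm in itertools.combinations(menses, m):
            for kk in itertools.combinations(nonmenses, k):
                yield mm + kk
    else:
        for rep in range(scheme.n_reps):
            rng = _rng_for(scheme, series.participant_id, rep)
            mm = rng.choice(menses, size=m, replace=False) if m else np.array([], dtype=int)
            kk = rng.choice(nonmenses, size=k, replace=False) if k else np.array([], dtype=int)
            yield tuple(int(d) for d in mm) + tuple(int(d) for d in kk)


def subsample_series(
    series: ParticipantSeries,
    scheme: SubsampleScheme,
    rep_index: int = 0,
    window: Tuple[int, int] = (9, 25),
) -> ParticipantSeries:
    """One deterministic random replicate of a scheme applied to a series."""
    if scheme.is_identity:
        return series
    menses, nonmenses = _pools(series, scheme, window)
    m = len(menses) if scheme.n_menses is None else scheme.n_menses
    k = len(nonmenses) if scheme.n_nonmenses is None else scheme.n_nonmenses
    if len(menses) < m or len(nonmenses) < k:
        raise InfeasibleSchemeError(
            f"{series.participant_id}: needs {m} menses / {k} menses-free days, "
            f"has {len(menses)} / {len(nonmenses)}"
        )
    rng = _rng_for(scheme, series.participant_id, rep_index)
    mm = rng.choice(menses, size=m, replace=False) if m else np.array([], dtype=int)
    kk = rng.choice(nonmenses, size=k, replace=False) if k else np.array([], dtype=int)
    return series.with_presence([int(d) for d in mm] + [int(d) for d in kk])


def every_kth_day_scheme(
    series: ParticipantSeries, k: int, offset: int = 0
) -> ParticipantSeries:
    """Retain present samples on cycle days congruent to ``offset`` mod ``k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    kept = [r.cycle_day for r in series.present_records if r.cycle_day % k == offset % k]
    return series.with_presence(kept)


@dataclasses.dataclass(frozen=True)
class AgreementReport:
    """Agreement between subsampled and full-series VCD labels."""

    scheme: SubsampleScheme
    overall_agreement: float
    per_vcd_agreement: Dict[str, float]
    n_evaluations: int
    n_infeasible: int
    n_reference_indeterminate: int

    def __post_init__(self) -> None:
        if self.n_evaluations <= 0:
            raise ValueError("AgreementReport requires at least one evaluation")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stratum": "overall",
                "agreement": self.overall_agreement,
                "n_evaluations": self.n_evaluations,
            }
        ]
        for vcd, agree in sorted(self.per_vcd_agreement.items()):
            rows.append({"stratum": vcd, "agreement": agree, "n_evaluations": None})
        return pd.DataFrame(rows)


def agreement_rate(
    cohort: Iterable[ParticipantSeries],
    scheme: SubsampleScheme,
    config: Optional[VcdConfig] = None,
) -> AgreementReport:
    """Fraction of (participant, replicate) evaluations recovering the label.

    Reference labels use the full guards; subsample labels relax the
    minimum-sample guards to one. Participants whose reference label is
    indeterminate, or for whom the scheme is infeasible, are counted and
    excluded.
    """
    config = config or VcdConfig()
    relaxed = config.relaxed()
    window = config.midcycle_window

    per_vcd_hits: Dict[str, int] = {}
    per_vcd_total: Dict[str, int] = {}
    n_eval = 0
    n_hit = 0
    n_infeasible = 0
    n_ref_indet = 0

    for series in cohort:
        ref_label, _ = classify_series(series, config)
        if ref_label is VcdLabel.INDETERMINATE:
            n_ref_indet += 1
            continue
        try:
            selections = list(iter_selections(series, scheme, window))
        except InfeasibleSchemeError:
            n_infeasible += 1
            continue
        if not selections:
            n_infeasible += 1
            continue
        for kept in selections:
            sub = series.with_presence(kept)
            sub_label, _ = classify_series(sub, relaxed)
            hit = sub_label is ref_label
            n_eval += 1
            n_hit += int(hit)
            per_vcd_total[ref_label.value] = per_vcd_total.get(ref_label.value, 0) + 1
            per_vcd_hits[ref_label.value] = per_vcd_hits.get(ref_label.value, 0) + int(hit)

    if n_eval == 0:
        raise InfeasibleSchemeError("all replicates infeasible for this cohort")
    per_vcd = {
        vcd: per_vcd_hits.get(vcd, 0) / total for vcd, total in per_vcd_total.items()
    }
    return AgreementReport(
        scheme=scheme,
        overall_agreement=n_hit / n_eval,
        per_vcd_agreement=per_vcd,
        n_evaluations=n_eval,
        n_infeasible=n_infeasible,
        n_reference_indeterminate=n_ref_indet,
    )


def scheme_frontier(
    cohort: Iterable[ParticipantSeries],
    config: Optional[VcdConfig] = None,
    target: float = 1.0,
    menses_grid: Sequence[int] = range(0, 5),
    nonmenses_grid: Sequence[int] = range(0, 7),
    seed: int = 0,
    n_reps: int = 200,
) -> List[Tuple[SubsampleScheme, AgreementReport]]:
    """Pareto-minimal schemes whose stratified agreement meets ``target``.

    A scheme qualifies when every VCD present in the (classifiable)
    cohort reaches agreement >= target. Among qualifying schemes, those
    dominated componentwise by a smaller qualifying scheme are removed.
    Returns an empty list, with a log report, when nothing qualifies.
    """
    if not (0 < target <= 1):
        raise ValueError(f"target must be in (0, 1], got {target}")
    cohort = list(cohort)
    config = config or VcdConfig()

    qualifying: Dict[Tuple[int, int], AgreementReport] = {}
    for m in menses_grid:
        for k in nonmenses_grid:
            if m + k == 0:
                continue
            scheme = SubsampleScheme(
                n_menses=m, n_nonmenses=k, seed=seed, n_reps=n_reps
            )
            try:
                report = agreement_rate(cohort, scheme, config)
            except InfeasibleSchemeError:
                continue
            if report.n_infeasible > 0:
                continue
            if all(a >= target for a in report.per_vcd_agreement.values()):
                qualifying[(m, k)] = report

    if not qualifying:
        logger.warning("no scheme on the grid meets stratified agreement %s", target)
        return []

    frontier = []
    for (m, k), report in sorted(qualifying.items()):
        dominated = any(
            (m2 <= m and k2 <= k and (m2, k2) != (m, k)) for (m2, k2) in qualifying
        )
        if not dominated:
            frontier.append((SubsampleScheme(n_menses=m, n_nonmenses=k, seed=seed, n_reps=n_reps), report))
    return frontier
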