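"""Domain types for daily vaginal-microbiome time series.

The central objects are :class:`CstLabel` (a community state type, CST,
as assigned by a nearest-centroid tool such as VALENCIA), per-day
:class:`SampleRecord` observations, a per-participant
:class:`ParticipantSeries` covering one menstrual cycle, and the
:class:`VcdConfig` thresholds that drive the vaginal community dynamics
(VCD) classifier.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "CstLabel",
    "CstParseError",
    "VcdLabel",
    "Branch",
    "SampleRecord",
    "ParticipantSeries",
    "VcdConfig",
    "VcdDiagnostics",
    "CountTable",
    "DEFAULT_DAY_RANGE",
]

MAIN_TYPES = ("I", "II", "III", "IV", "V")
SUB_TYPES = ("A", "B", "C")

#: Declared sampling range: cycle day 4 through 32, day 1 = first day of menses.
DEFAULT_DAY_RANGE = (4, 32)

# Longest roman numerals first so "IV" is not consumed as "I".
_CST_RE = re.compile(r"^(III|II|IV|I|V)\s*[-_ ]?\s*([A-C])?$")


class CstParseError(ValueError):
    """Raised when a CST token cannot be interpreted."""


@dataclasses.dataclass(frozen=True, order=True)
class CstLabel:
    """A community state type, e.g. CST III-B.

    ``main`` is the Roman-numeral main type (I-V); ``sub`` the optional
    subtype letter (A-C). Input dialects "III-A", "IIIA", "III_A" and
    "III A" all parse to the same value.
    """

    main: str
    sub: Optional[str] = None

    def __post_init__(self) -> None:
        if self.main not in MAIN_TYPES:
            raise CstParseError(f"unknown CST main type: {self.main!r}")
        if self.sub is not None and self.sub not in SUB_TYPES:
            raise CstParseError(f"unknown CST subtype: {self.sub!r}")

    @classmethod
    def parse(cls, token: str) -> "CstLabel":
        if not isinstance(token, str):
            raise CstParseError(f"CST token must be a string, got {token!r}")
        m = _CST_RE.match(token.strip().upper())
        if m is None:
            raise CstParseError(f"unknown CST: {token!r}")
        return cls(main=m.group(1), sub=m.group(2))

    def __str__(self) -> str:
        return self.main if self.sub is None else f"{self.main}-{self.sub}"


class VcdLabel(str, Enum):
    """The four vaginal community dynamics, plus an explicit indeterminate."""

    CONSTANT_EUBIOTIC = "constant_eubiotic"
    MENSES_RELATED = "menses_related_dysbiotic"
    UNSTABLE = "unstable"
    CONSTANT_DYSBIOTIC = "constant_dysbiotic"
    INDETERMINATE = "indeterminate"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Branch(str, Enum):
    """Which branch of the decision tree produced a label."""

    TOP_EUBIOTIC = "top_eubiotic"
    TOP_DYSBIOTIC = "top_dysbiotic"
    MID_EUBIOTIC = "mid_eubiotic"
    MID_OTHER = "mid_other"
    INSUFFICIENT = "insufficient"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    """One day's observation for one participant.

    ``present=False`` marks a day with no sequenced sample; such records
    carry no CST but keep the diary flags (bleeding, intercourse) so that
    denominators and menses definitions stay unambiguous.
    """

    participant_id: str
    cycle_day: int
    cst: Optional[CstLabel] = None
    bleeding: bool = False
    intercourse: bool = False
    present: bool = True
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if int(self.cycle_day) < 1:
            raise ValueError(f"cycle_day must be >= 1, got {self.cycle_day}")
        if self.present and self.cst is None:
            raise ValueError(
                f"present sample {self.participant_id} day {self.cycle_day} has no CST"
            )
        if not self.present and self.cst is not None:
            raise ValueError(
                f"absent sample {self.participant_id} day {self.cycle_day} carries a CST"
            )


@dataclasses.dataclass(frozen=True)
class ParticipantSeries:
    """An ordered daily series of records for one participant."""

    participant_id: str
    records: tuple
    day_range: tuple = DEFAULT_DAY_RANGE

    def __post_init__(self) -> None:
        recs = tuple(sorted(self.records, key=lambda r: r.cycle_day))
        object.__setattr__(self, "records", recs)
        days = [r.cycle_day for r in recs]
        if len(set(days)) != len(days):
            dupes = sorted({d for d in days if days.count(d) > 1})
            raise ValueError(
                f"duplicate cycle days for {self.participant_id}: {dupes}"
            )
        for r in recs:
            if r.participant_id != self.participant_id:
                raise ValueError(
                    f"record for {r.participant_id} in series {self.participant_id}"
                )

    @property
    def present_records(self) -> tuple:
        return tuple(r for r in self.records if r.present)

    @property
    def n_present(self) -> int:
        return len(self.present_records)

    def in_window(self, window: tuple) -> tuple:
        lo, hi = window
        return tuple(r for r in self.present_records if lo <= r.cycle_day <= hi)

    def with_presence(self, keep_days: Iterable[int]) -> "ParticipantSeries":
        """Return a copy where only ``keep_days`` remain present.

        Days outside ``keep_days`` become explicit absent records; diary
        flags are preserved so menses membership survives subsampling.
        """
        keep = set(keep_days)
        new = []
        for r in self.records:
            if r.present and r.cycle_day not in keep:
                new.append(dataclasses.replace(r, present=False, cst=None))
            else:
                new.append(r)
        return ParticipantSeries(self.participant_id, tuple(new), self.day_range)


def _to_fraction(x) -> Fraction:
    """Exact threshold conversion; 0.8 becomes 4/5, not the nearest double."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(str(x))
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot interpret threshold {x!r}")


@dataclasses.dataclass(frozen=True)
class VcdConfig:
    """Thresholds and windows for the VCD decision tree.

    The defaults mirror the published tree: eubiotic CSTs {I, II, V};
    a series is constant eubiotic when >= 80% of present samples are
    eubiotic, constant dysbiotic when > 80% are dysbiotic (note the
    asymmetric boundary, kept configurable), and otherwise the call is
    made on the menses-free window (cycle days 9-25): > 80% eubiotic
    there means menses-related dysbiotic, else unstable.
    """

    eubiotic_csts: frozenset = frozenset({"I", "II", "V"})
    constant_eubiotic_min_frac: Fraction = Fraction(4, 5)
    constant_eubiotic_inclusive: bool = True
    constant_dysbiotic_min_frac: Fraction = Fraction(4, 5)
    constant_dysbiotic_inclusive: bool = False
    midcycle_window: tuple = (9, 25)
    midcycle_eubiotic_min_frac: Fraction = Fraction(4, 5)
    midcycle_eubiotic_inclusive: bool = False
    min_samples_total: int = 5
    min_samples_midcycle: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "eubiotic_csts", frozenset(self.eubiotic_csts))
        for name in (
            "constant_eubiotic_min_frac",
            "constant_dysbiotic_min_frac",
            "midcycle_eubiotic_min_frac",
        ):
            frac = _to_fraction(getattr(self, name))
            if not (0 < frac <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {frac}")
            object.__setattr__(self, name, frac)
        bad = set(self.eubiotic_csts) - set(MAIN_TYPES)
        if bad:
            raise ValueError(f"unknown CST main types in eubiotic set: {sorted(bad)}")
        lo, hi = self.midcycle_window
        if lo > hi:
            raise ValueError(f"empty mid-cycle window {self.midcycle_window}")
        if self.min_samples_total < 1 or self.min_samples_midcycle < 1:
            raise ValueError("minimum sample counts must be >= 1")

    def relaxed(self) -> "VcdConfig":
        """Copy with sample-count guards lowered to 1 (for tiny subsamples)."""
        return dataclasses.replace(self, min_samples_total=1, min_samples_midcycle=1)

    def to_dict(self) -> dict:
        return {
            "eubiotic_csts": sorted(self.eubiotic_csts),
            "constant_eubiotic_min_frac": str(self.constant_eubiotic_min_frac),
            "constant_eubiotic_inclusive": self.constant_eubiotic_inclusive,
            "constant_dysbiotic_min_frac": str(self.constant_dysbiotic_min_frac),
            "constant_dysbiotic_inclusive": self.constant_dysbiotic_inclusive,
            "midcycle_window": list(self.midcycle_window),
            "midcycle_eubiotic_min_frac": str(self.midcycle_eubiotic_min_frac),
            "midcycle_eubiotic_inclusive": self.midcycle_eubiotic_inclusive,
            "min_samples_total": self.min_samples_total,
            "min_samples_midcycle": self.min_samples_midcycle,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VcdConfig":
        d = dict(d)
        if "midcycle_window" in d:
            d["midcycle_window"] = tuple(d["midcycle_window"])
        if "eubiotic_csts" in d:
            d["eubiotic_csts"] = frozenset(d["eubiotic_csts"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclasses.dataclass(frozen=True)
class VcdDiagnostics:
    """Per-series counts and fractions backing a VCD call."""

    n_present: int
    n_eubiotic: int
    frac_eubiotic_total: Optional[Fraction]
    n_midcycle_present: int
    n_midcycle_eubiotic: int
    frac_eubiotic_midcycle: Optional[Fraction]
    branch_taken: Branch

    def __post_init__(self) -> None:
        if self.n_eubiotic > self.n_present:
            raise ValueError("n_eubiotic cannot exceed n_present")
        for frac in (self.frac_eubiotic_total, self.frac_eubiotic_midcycle):
            if frac is not None and not (0 <= frac <= 1):
                raise ValueError(f"fraction out of [0,1]: {frac}")


@dataclasses.dataclass
class CountTable:
    """A taxa-by-samples count matrix with non-negative entries."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("CountTable wraps a pandas DataFrame (taxa x samples)")
        values = df.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("count table contains negative entries")

    @property
    def taxa(self) -> Sequence[str]:
        return list(self.data.index)

    @property
    def samples(self) -> Sequence[str]:
        return list(self.data.columns)

    def column(self, sample_id: str):
        return self.data[sample_id].to_numpy(dtype=float)

    def require_positive_sums(self, sample_ids: Optional[Iterable[str]] = None) -> None:
        cols = list(sample_ids) if sample_ids is not None else list(self.data.columns)
        sums = self.data[cols].sum(axis=0)
        empty = sums[sums <= 0]
        if len(empty):
            raise ValueError(f"samples with zero total counts: {list(empty.index)}")
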