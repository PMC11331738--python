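"""Readers and writers for CST tables, diary metadata, counts and VCD output.

Input formats follow common practice in vaginal-microbiome studies: a
VALENCIA-style CSV/TSV of per-sample CST assignments, a diary metadata
TSV (participant, sample, cycle day, bleeding and intercourse flags) and
taxa-by-samples count TSVs. All parsing is strict: unknown CST tokens,
duplicate days and orphan samples are errors with row context, never
silent drops.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .types import (
    DEFAULT_DAY_RANGE,
    CountTable,
    CstLabel,
    CstParseError,
    ParticipantSeries,
    SampleRecord,
    VcdConfig,
)

__all__ = [
    "read_cst_table",
    "read_metadata",
    "merge_series",
    "write_vcd_assignments",
    "read_vcd_assignments",
    "read_count_table",
]

_SAMPLE_COLS = ("sampleid", "sample_id", "sample", "samplename")
_SUBCST_COLS = ("subcst", "sub_cst")
_CST_COLS = ("cst",)
_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _find_column(header: Sequence[str], candidates: Sequence[str]) -> Optional[str]:
    lowered = {col.lower().strip(): col for col in header}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def _parse_bool(token, path: Path, row_num: int, column: str) -> bool:
    text = str(token).strip().lower()
    if text in _TRUE_TOKENS:
        return True
    if text in _FALSE_TOKENS:
        return False
    raise ValueError(
        f"{path}:{row_num}: unknown boolean token {token!r} in column {column}"
    )


def read_cst_table(path, dialect: Optional[str] = None) -> List[Tuple[str, CstLabel]]:
    """Read per-sample CST assignments from a VALENCIA-style table.

    Uses the subCST column when present (it carries the subtype),
    otherwise the CST column. ``dialect`` may force ``"csv"`` or
    ``"tsv"``; by default the file extension decides.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t", None: _sep_for(path)}[dialect]
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter=sep)
        header = reader.fieldnames or []
        sample_col = _find_column(header, _SAMPLE_COLS)
        cst_col = _find_column(header, _SUBCST_COLS) or _find_column(header, _CST_COLS)
        if sample_col is None or cst_col is None:
            raise ValueError(
                f"{path}: need a sample column ({'/'.join(_SAMPLE_COLS)}) and a "
                f"CST or subCST column; found {header}"
            )
        out: List[Tuple[str, CstLabel]] = []
        for row_num, row in enumerate(reader, start=2):
            sample_id = (row[sample_col] or "").strip()
            token = (row[cst_col] or "").strip()
            if not sample_id:
                raise ValueError(f"{path}:{row_num}: empty sample id")
            try:
                label = CstLabel.parse(token)
            except CstParseError as exc:
                raise CstParseError(f"{path}:{row_num}: {exc}") from exc
            out.append((sample_id, label))
    return out


def read_metadata(path) -> List[SampleRecord]:
    """Read the diary metadata TSV into absent-by-default sample records.

    Required columns: participant_id, sample_id, cycle_day, bleeding,
    intercourse. Records come back grouped by participant and sorted by
    day; duplicate (participant, cycle_day) pairs are errors.
    """
    path = Path(path)
    records: List[SampleRecord] = []
    seen_days: Dict[Tuple[str, int], int] = {}
    seen_samples: Dict[str, int] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter=_sep_for(path))
        header = reader.fieldnames or []
        required = ("participant_id", "sample_id", "cycle_day", "bleeding", "intercourse")
        missing = [c for c in required if _find_column(header, (c,)) is None]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        cols = {c: _find_column(header, (c,)) for c in required}
        for row_num, row in enumerate(reader, start=2):
            pid = row[cols["participant_id"]].strip()
            sid = (row[cols["sample_id"]] or "").strip() or None
            try:
                day = int(str(row[cols["cycle_day"]]).strip())
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{row_num}: non-integer cycle_day {row[cols['cycle_day']]!r}"
                ) from exc
            key = (pid, day)
            if key in seen_days:
                raise ValueError(
                    f"{path}:{row_num}: duplicate (participant, cycle_day) {key}, "
                    f"first seen at line {seen_days[key]}"
                )
            seen_days[key] = row_num
            if sid is not None:
                if sid in seen_samples:
                    raise ValueError(
                        f"{path}:{row_num}: duplicate sample_id {sid!r}, "
                        f"first seen at line {seen_samples[sid]}"
                    )
                seen_samples[sid] = row_num
            records.append(
                SampleRecord(
                    participant_id=pid,
                    cycle_day=day,
                    cst=None,
                    bleeding=_parse_bool(row[cols["bleeding"]], path, row_num, "bleeding"),
                    intercourse=_parse_bool(
                        row[cols["intercourse"]], path, row_num, "intercourse"
                    ),
                    present=False,
                    sample_id=sid,
                )
            )
    records.sort(key=lambda r: (r.participant_id, r.cycle_day))
    return records


def merge_series(
    cst_assignments: Iterable[Tuple[str, CstLabel]],
    metadata: Iterable[SampleRecord],
    declared_range: Tuple[int, int] = DEFAULT_DAY_RANGE,
) -> List[ParticipantSeries]:
    """Join CST calls onto diary metadata, one full-length series per participant.

    Every day of ``declared_range`` yields a record: present with a CST
    when the day's sample was assigned one, absent otherwise (keeping
    diary flags when known). CST samples that match no metadata row are
    an error listing the orphans.
    """
    cst_map = dict(cst_assignments)
    if len(cst_map) == 0:
        raise ValueError("no classifiable samples: CST table is empty")
    meta = list(metadata)
    by_sample = {r.sample_id: r for r in meta if r.sample_id is not None}
    orphans = sorted(set(cst_map) - set(by_sample))
    if orphans:
        raise ValueError(f"CST samples with no metadata match: {orphans}")

    by_participant: Dict[str, Dict[int, SampleRecord]] = {}
    for rec in meta:
        by_participant.setdefault(rec.participant_id, {})[rec.cycle_day] = rec

    lo, hi = declared_range
    out = []
    for pid in sorted(by_participant):
        day_map = by_participant[pid]
        records = []
        for day in range(lo, hi + 1):
            base = day_map.get(day)
            if base is None:
                records.append(
                    SampleRecord(participant_id=pid, cycle_day=day, present=False)
                )
                continue
            cst = cst_map.get(base.sample_id) if base.sample_id else None
            if cst is not None:
                records.append(
                    SampleRecord(
                        participant_id=pid,
                        cycle_day=day,
                        cst=cst,
                        bleeding=base.bleeding,
                        intercourse=base.intercourse,
                        present=True,
                        sample_id=base.sample_id,
                    )
                )
            else:
                records.append(base)
        # Diary days outside the declared range are dropped; assigned CSTs
        # there would otherwise vanish silently, so keep them as extra days.
        extra = [
            d
            for d, rec in sorted(day_map.items())
            if (d < lo or d > hi) and rec.sample_id in cst_map
        ]
        for day in extra:
            base = day_map[day]
            records.append(
                SampleRecord(
                    participant_id=pid,
                    cycle_day=day,
                    cst=cst_map[base.sample_id],
                    bleeding=base.bleeding,
                    intercourse=base.intercourse,
                    present=True,
                    sample_id=base.sample_id,
                )
            )
        out.append(ParticipantSeries(pid, tuple(records), declared_range))
    return out


_VCD_COLUMNS = [
    "participant_id",
    "vcd",
    "n_samples",
    "eubiotic_frac_total",
    "eubiotic_frac_midcycle",
    "config_hash",
]


def write_vcd_assignments(assignments: pd.DataFrame, path, config: Optional[VcdConfig] = None) -> None:
    """Write a classify_cohort table as a deterministic TSV.

    Fractions are serialized with full repr precision so write/read
    round-trips exactly; rows are sorted by participant id.
    """
    config = config or VcdConfig()
    path = Path(path)
    table = assignments.copy()
    table["config_hash"] = config.config_hash()
    table = table.sort_values("participant_id")
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_VCD_COLUMNS)
        for _, row in table.iterrows():
            writer.writerow(
                [
                    row["participant_id"],
                    row["vcd"],
                    int(row["n_samples"]),
                    repr(float(row["eubiotic_frac_total"])),
                    repr(float(row["eubiotic_frac_midcycle"])),
                    row["config_hash"],
                ]
            )


def read_vcd_assignments(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_vcd_assignments`."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    missing = [c for c in _VCD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing VCD columns {missing}")
    return df


def read_count_table(path, orientation: str = "taxa_by_samples") -> CountTable:
    """Read a TSV count matrix; ``orientation`` may flip samples-by-taxa input."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_by_taxa":
        df = df.T
    elif orientation != "taxa_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    return CountTable(df)
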