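"""Synthetic cohorts with known ground-truth dynamics.

The generator emulates one menstrual cycle of daily vaginal sampling:
an event calendar (menses, intercourse, missed samples), a two-state
(eubiotic/dysbiotic) Markov chain per participant whose daily switch
probabilities depend on bleeding and intercourse, CST-conditional
Dirichlet-multinomial compositions over a nine-taxon panel, and censored
log-normal phage-to-bacteria ratios. Regime presets live in
``data/regime_presets.yaml``; the minimal two-state chain is a testing
stand-in, not a biological model.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .types import (
    DEFAULT_DAY_RANGE,
    CountTable,
    CstLabel,
    ParticipantSeries,
    SampleRecord,
    VcdLabel,
)

__all__ = [
    "CalendarParams",
    "RegimeParams",
    "CompositionModel",
    "PhageModel",
    "CohortBundle",
    "load_regime_presets",
    "simulate_calendar",
    "simulate_trajectory",
    "simulate_composition",
    "simulate_phage_ratios",
    "simulate_cohort",
    "DEFAULT_MIX",
]

#: Cohort mix used by default: constant eubiotic, menses-related,
#: unstable, constant dysbiotic.
DEFAULT_MIX = {
    "constant_eubiotic": 20,
    "menses_related_dysbiotic": 6,
    "unstable": 11,
    "constant_dysbiotic": 12,
}


@dataclasses.dataclass(frozen=True)
class CalendarParams:
    """Cycle geometry and sampling behaviour.

    ``missingness_rate`` defaults to 0.08, reproducing an average of
    about 25.9 successfully sequenced samples over a 28-day daily
    sampling effort.
    """

    cycle_length: int = 28
    menses_days: int = 5
    day_range: Tuple[int, int] = DEFAULT_DAY_RANGE
    missingness_rate: float = 0.08
    intercourse_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.menses_days >= self.cycle_length:
            raise ValueError("menses_days must be shorter than the cycle")
        for name in ("missingness_rate", "intercourse_rate"):
            rate = getattr(self, name)
            if not (0 <= rate <= 1):
                raise ValueError(f"{name} must be in [0,1], got {rate}")


@dataclasses.dataclass(frozen=True)
class RegimeParams:
    """Daily transition probabilities for one dynamics regime.

    From the eubiotic state the chain switches to dysbiosis with
    ``p_dysbiosis_menses`` on bleeding days, ``p_dysbiosis_intercourse``
    on intercourse days and ``p_dysbiosis_spont`` otherwise; from the
    dysbiotic state it recovers with ``p_recover``. The state is then
    decorated with a CST subtype drawn from the matching distribution.
    """

    regime: str
    p_dysbiosis_menses: float
    p_dysbiosis_spont: float
    p_dysbiosis_intercourse: float
    p_recover: float
    start_dysbiotic: bool = False
    eubiotic_cst_dist: Tuple[Tuple[str, float], ...] = (
        ("I-A", 0.60),
        ("I-B", 0.25),
        ("V", 0.15),
    )
    dysbiotic_cst_dist: Tuple[Tuple[str, float], ...] = (
        ("III-A", 0.25),
        ("III-B", 0.15),
        ("IV-A", 0.15),
        ("IV-B", 0.35),
        ("IV-C", 0.10),
    )

    def __post_init__(self) -> None:
        for name in (
            "p_dysbiosis_menses",
            "p_dysbiosis_spont",
            "p_dysbiosis_intercourse",
            "p_recover",
        ):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be a probability, got {p}")
        for dist_name in ("eubiotic_cst_dist", "dysbiotic_cst_dist"):
            dist = tuple(tuple(item) for item in getattr(self, dist_name))
            object.__setattr__(self, dist_name, dist)
            total = sum(w for _, w in dist)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{dist_name} weights sum to {total}, not 1")


def load_regime_presets(path: Optional[Path] = None) -> Dict[str, RegimeParams]:
    """Load the versioned regime presets shipped with the package."""
    if path is None:
        source = importlib.resources.files("vcdkit").joinpath("data/regime_presets.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    presets = {}
    for regime, params in raw["regimes"].items():
        kwargs = dict(params)
        for dist_name in ("eubiotic_cst_dist", "dysbiotic_cst_dist"):
            if dist_name in kwargs:
                kwargs[dist_name] = tuple(
                    (str(cst), float(w)) for cst, w in kwargs[dist_name].items()
                )
        presets[regime] = RegimeParams(regime=regime, **kwargs)
    return presets


DEFAULT_TAXA = (
    "Lactobacillus crispatus",
    "Lactobacillus iners",
    "Lactobacillus gasseri",
    "Lactobacillus jensenii",
    "Gardnerella spp.",
    "Prevotella spp.",
    "Fannyhessea vaginae",
    "Sneathia spp.",
    "Other",
)

_DEFAULT_CONCENTRATIONS = {
    "I": (30.0, 1.5, 0.3, 0.3, 0.4, 0.3, 0.1, 0.1, 1.0),
    "II": (1.0, 1.0, 30.0, 0.3, 0.4, 0.3, 0.1, 0.1, 1.0),
    "III": (1.0, 30.0, 0.3, 0.3, 1.5, 1.0, 0.3, 0.2, 1.0),
    "IV": (0.4, 2.0, 0.3, 0.3, 15.0, 10.0, 3.0, 2.0, 2.0),
    "V": (1.0, 1.0, 0.3, 30.0, 0.4, 0.3, 0.1, 0.1, 1.0),
}


@dataclasses.dataclass(frozen=True)
class CompositionModel:
    """CST-conditional Dirichlet-multinomial composition generator."""

    taxa: Tuple[str, ...] = DEFAULT_TAXA
    concentrations: Mapping[str, Tuple[float, ...]] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_CONCENTRATIONS)
    )
    library_size_log_mean: float = np.log(2e4)
    library_size_log_sd: float = 0.4

    def __post_init__(self) -> None:
        for cst, conc in self.concentrations.items():
            if len(conc) != len(self.taxa):
                raise ValueError(f"concentration vector for CST {cst} has wrong length")
            if any(c <= 0 for c in conc):
                raise ValueError(f"concentrations must be positive (CST {cst})")

    def dirichlet_mean(self, main_type: str) -> np.ndarray:
        conc = np.asarray(self.concentrations[main_type], dtype=float)
        return conc / conc.sum()


@dataclasses.dataclass(frozen=True)
class PhageModel:
    """Censored log-normal phage-to-bacteria ratio generator.

    ``location``/``scale`` are natural-log parameters per (regime,
    state-class) pair; draws below ``detection_limit`` are reported as
    non-detects (ratio 0.0, censored flag), and detects are clipped at
    ``ceiling``. ``switch_boost`` adds to the log-location on days whose
    eubiotic/dysbiotic state differs from the participant's majority
    state, emulating phage blooms at community transitions.
    """

    params: Mapping[Tuple[str, str], Tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {
            ("constant_eubiotic", "eubiotic"): (np.log(1e-3), 1.0),
            ("constant_eubiotic", "dysbiotic"): (np.log(1e-3), 1.0),
            ("menses_related_dysbiotic", "eubiotic"): (np.log(8e-5), 1.0),
            ("menses_related_dysbiotic", "dysbiotic"): (np.log(1.5e-4), 1.0),
            ("unstable", "eubiotic"): (np.log(1e-4), 1.0),
            ("unstable", "dysbiotic"): (np.log(2e-4), 1.0),
            ("constant_dysbiotic", "eubiotic"): (np.log(8e-5), 1.0),
            ("constant_dysbiotic", "dysbiotic"): (np.log(1e-4), 1.0),
        }
    )
    detection_limit: float = 1e-5
    ceiling: float = 2.7e-2
    switch_boost: float = np.log(5.0)

    def __post_init__(self) -> None:
        if not (self.detection_limit < self.ceiling):
            raise ValueError("detection_limit must be below ceiling")


def simulate_calendar(params: CalendarParams, seed: int) -> pd.DataFrame:
    """Per-day flags for one participant: bleeding, intercourse, sampled.

    Bleeding is deterministic from the cycle geometry (days
    1..menses_days of each cycle); intercourse and missingness are
    i.i.d. Bernoulli draws from one seeded generator.
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.day_range
    days = np.arange(lo, hi + 1)
    bleeding = ((days - 1) % params.cycle_length) + 1 <= params.menses_days
    intercourse = rng.random(days.size) < params.intercourse_rate
    sampled = rng.random(days.size) >= params.missingness_rate
    return pd.DataFrame(
        {"cycle_day": days, "bleeding": bleeding, "intercourse": intercourse, "sampled": sampled}
    )


def _draw_cst(rng: np.random.Generator, dist: Tuple[Tuple[str, float], ...]) -> CstLabel:
    tokens = [t for t, _ in dist]
    weights = np.array([w for _, w in dist], dtype=float)
    token = tokens[rng.choice(len(tokens), p=weights / weights.sum())]
    return CstLabel.parse(token)


def simulate_trajectory(
    calendar: pd.DataFrame,
    regime: RegimeParams,
    seed: int,
    participant_id: str = "SIM",
    day_range: Tuple[int, int] = DEFAULT_DAY_RANGE,
    cycle_length: int = 28,
    menses_days: int = 5,
) -> ParticipantSeries:
    """Run the decorated two-state chain over one cycle.

    The chain is iterated from cycle day 1 so that the first menses
    (days 1..menses_days) can shape the state before the first emitted
    day; only days inside ``day_range`` produce records, and only
    sampled days are present.
    """
    rng = np.random.default_rng(seed)
    lo, hi = day_range
    cal = calendar.set_index("cycle_day")

    state_dysbiotic = regime.start_dysbiotic
    records: List[SampleRecord] = []
    for day in range(1, hi + 1):
        in_range = lo <= day <= hi
        if in_range and day in cal.index:
            bleeding = bool(cal.loc[day, "bleeding"])
            intercourse = bool(cal.loc[day, "intercourse"])
            sampled = bool(cal.loc[day, "sampled"])
        else:
            bleeding = ((day - 1) % cycle_length) + 1 <= menses_days
            intercourse = False
            sampled = False

        # Recovery is evaluated first; a participant recovering on a
        # trigger day is immediately exposed to that day's trigger again,
        # so sustained menses keep a susceptible chain dysbiotic.
        if state_dysbiotic and rng.random() < regime.p_recover:
            state_dysbiotic = False
        if not state_dysbiotic:
            if bleeding:
                p_switch = regime.p_dysbiosis_menses
            elif intercourse:
                p_switch = regime.p_dysbiosis_intercourse
            else:
                p_switch = regime.p_dysbiosis_spont
            if rng.random() < p_switch:
                state_dysbiotic = True

        if not in_range:
            continue
        if sampled:
            dist = regime.dysbiotic_cst_dist if state_dysbiotic else regime.eubiotic_cst_dist
            records.append(
                SampleRecord(
                    participant_id=participant_id,
                    cycle_day=day,
                    cst=_draw_cst(rng, dist),
                    bleeding=bleeding,
                    intercourse=intercourse,
                    present=True,
                    sample_id=f"{participant_id}_d{day:02d}",
                )
            )
        else:
            records.append(
                SampleRecord(
                    participant_id=participant_id,
                    cycle_day=day,
                    bleeding=bleeding,
                    intercourse=intercourse,
                    present=False,
                )
            )
    return ParticipantSeries(participant_id, tuple(records), day_range)


def simulate_composition(
    series: ParticipantSeries, model: CompositionModel, seed: int
) -> CountTable:
    """Dirichlet-multinomial counts for every present sample of a series."""
    rng = np.random.default_rng(seed)
    columns = {}
    for rec in series.present_records:
        conc = np.asarray(model.concentrations[rec.cst.main], dtype=float)
        p = rng.dirichlet(conc)
        library = int(np.round(rng.lognormal(model.library_size_log_mean, model.library_size_log_sd)))
        library = max(library, 1)
        columns[rec.sample_id or f"{series.participant_id}_d{rec.cycle_day:02d}"] = (
            rng.multinomial(library, p)
        )
    df = pd.DataFrame(columns, index=list(model.taxa))
    return CountTable(df)


def simulate_phage_ratios(
    series: ParticipantSeries,
    model: PhageModel,
    seed: int,
    regime_label: str,
    eubiotic_mains: Iterable[str] = ("I", "II", "V"),
) -> pd.DataFrame:
    """Per-sample phage-to-bacteria ratios with explicit non-detects.

    Returns a frame with columns sample_id, participant_id, cycle_day,
    ratio, censored. Censored rows carry ratio 0.0.
    """
    rng = np.random.default_rng(seed)
    eub = set(eubiotic_mains)
    states = [
        "eubiotic" if r.cst.main in eub else "dysbiotic" for r in series.present_records
    ]
    if not states:
        return pd.DataFrame(
            columns=["sample_id", "participant_id", "cycle_day", "ratio", "censored"]
        )
    n_eub = sum(s == "eubiotic" for s in states)
    majority = "eubiotic" if n_eub * 2 >= len(states) else "dysbiotic"
    rows = []
    for rec, state in zip(series.present_records, states):
        mu, sigma = model.params[(regime_label, state)]
        if state != majority:
            mu = mu + model.switch_boost
        draw = float(np.exp(mu + sigma * rng.standard_normal()))
        draw = min(draw, model.ceiling)
        censored = draw < model.detection_limit
        rows.append(
            {
                "sample_id": rec.sample_id,
                "participant_id": rec.participant_id,
                "cycle_day": rec.cycle_day,
                "ratio": 0.0 if censored else draw,
                "censored": censored,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "participant_id", "cycle_day", "ratio", "censored"])


@dataclasses.dataclass
class CohortBundle:
    """Everything one simulated cohort produces, with ground truth."""

    series: List[ParticipantSeries]
    truth: Dict[str, str]
    counts: CountTable
    phage: pd.DataFrame

    def write(self, outdir) -> None:
        """Write cst.csv, meta.tsv, counts.tsv, phage.tsv and truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cst_rows = []
        meta_rows = []
        for series in self.series:
            for rec in series.records:
                if rec.present:
                    cst_rows.append(
                        {"sampleID": rec.sample_id, "CST": rec.cst.main, "subCST": str(rec.cst)}
                    )
                meta_rows.append(
                    {
                        "participant_id": rec.participant_id,
                        "sample_id": rec.sample_id or "",
                        "cycle_day": rec.cycle_day,
                        "bleeding": int(rec.bleeding),
                        "intercourse": int(rec.intercourse),
                    }
                )
        pd.DataFrame(cst_rows).to_csv(outdir / "cst.csv", index=False)
        pd.DataFrame(meta_rows).to_csv(outdir / "meta.tsv", sep="\t", index=False)
        self.counts.data.to_csv(outdir / "counts.tsv", sep="\t")
        self.phage.to_csv(outdir / "phage.tsv", sep="\t", index=False)
        truth = pd.DataFrame(
            sorted(self.truth.items()), columns=["participant_id", "regime"]
        )
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_cohort(
    mix: Optional[Mapping[str, int]] = None,
    params: Optional[CalendarParams] = None,
    seed: int = 0,
    presets: Optional[Mapping[str, RegimeParams]] = None,
    composition_model: Optional[CompositionModel] = None,
    phage_model: Optional[PhageModel] = None,
    with_compositions: bool = True,
) -> CohortBundle:
    """Simulate a full cohort bundle from a regime mix.

    All randomness flows from ``seed`` through per-participant child
    seeds, so bundles are bit-reproducible.
    """
    mix = dict(mix) if mix is not None else dict(DEFAULT_MIX)
    if not mix or sum(mix.values()) == 0:
        raise ValueError("empty cohort mix")
    params = params or CalendarParams()
    presets = presets or load_regime_presets()
    composition_model = composition_model or CompositionModel()
    phage_model = phage_model or PhageModel()

    root = np.random.default_rng(seed)
    series_list: List[ParticipantSeries] = []
    truth: Dict[str, str] = {}
    count_frames = []
    phage_frames = []
    idx = 0
    for regime_name in sorted(mix):
        n = mix[regime_name]
        if regime_name not in presets:
            raise ValueError(f"no preset for regime {regime_name!r}")
        for _ in range(n):
            idx += 1
            pid = f"P{idx:03d}"
            child = root.spawn(1)[0]
            sub_seeds = child.integers(0, 2**31 - 1, size=3)
            calendar = simulate_calendar(params, int(sub_seeds[0]))
            series = simulate_trajectory(
                calendar,
                presets[regime_name],
                int(sub_seeds[1]),
                participant_id=pid,
                day_range=params.day_range,
                cycle_length=params.cycle_length,
                menses_days=params.menses_days,
            )
            series_list.append(series)
            truth[pid] = regime_name
            if with_compositions and series.n_present:
                counts = simulate_composition(series, composition_model, int(sub_seeds[2]))
                count_frames.append(counts.data)
                phage_frames.append(
                    simulate_phage_ratios(
                        series, phage_model, int(sub_seeds[2]) + 1, regime_name
                    )
                )
    counts = CountTable(
        pd.concat(count_frames, axis=1) if count_frames else pd.DataFrame(index=list(composition_model.taxa))
    )
    phage = (
        pd.concat(phage_frames, ignore_index=True)
        if phage_frames
        else pd.DataFrame(columns=["sample_id", "participant_id", "cycle_day", "ratio", "censored"])
    )
    return CohortBundle(series=series_list, truth=truth, counts=counts, phage=phage)
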