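"""Dispersion, correlation, prevalence and resampling statistics.

Beta-diversity is compositional: the quantitative metric is the
Aitchison distance (Euclidean distance between centred log-ratio
transformed counts) and the qualitative one is Jaccard dissimilarity on
presence sets, where a taxon counts as present at >= 0.5% of a sample's
reads. Group comparisons across dynamics categories use a
subsample-then-Kruskal-Wallis rule (each participant reduced to at most
m samples, 10 trials; significant when p < alpha in at least 7 of 10)
with a Dunn post-hoc on the pooled data, all multiplicity-corrected with
Benjamini-Hochberg.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CountTable, ParticipantSeries

__all__ = [
    "DistanceSpec",
    "ResampleTestSpec",
    "ResampledTestResult",
    "clr_transform",
    "aitchison_distance",
    "jaccard_distance",
    "pairwise_distances",
    "participant_dispersion",
    "dispersion_by_participant",
    "event_correlation",
    "neighbor_distance",
    "phage_distance_correlation",
    "prevalence_test",
    "resampled_group_test",
    "dunn_posthoc",
    "bh_adjust",
]


@dataclasses.dataclass(frozen=True)
class DistanceSpec:
    """Which beta-diversity metric to use, and its knobs.

    ``pseudocount`` is added to raw counts before the CLR transform
    (Aitchison only; 0 is allowed only when all entries are positive).
    ``presence_threshold`` is the relative-abundance cutoff defining
    presence for the Jaccard metric and the prevalence test.
    """

    metric: str = "aitchison"
    pseudocount: float = 1.0
    presence_threshold: float = 0.005

    def __post_init__(self) -> None:
        if self.metric not in ("aitchison", "jaccard"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not (0 <= self.presence_threshold < 1):
            raise ValueError("presence_threshold must be in [0, 1)")


def clr_transform(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centred log-ratio transform: log((x+pc)/g(x+pc)); sums to ~0."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    x = x + pseudocount
    if (x <= 0).any():
        raise ValueError("all-zero entries require a positive pseudocount")
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


def aitchison_distance(
    sample_a: np.ndarray, sample_b: np.ndarray, spec: Optional[DistanceSpec] = None
) -> float:
    """Euclidean distance between CLR-transformed count vectors."""
    spec = spec or DistanceSpec()
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must share one taxon index")
    return float(
        np.linalg.norm(clr_transform(a, spec.pseudocount) - clr_transform(b, spec.pseudocount))
    )


def _presence(counts: np.ndarray, threshold: float) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        return np.zeros_like(x, dtype=bool)
    return (x / total) >= threshold


def jaccard_distance(
    sample_a: np.ndarray, sample_b: np.ndarray, spec: Optional[DistanceSpec] = None
) -> float:
    """1 - |A∩B|/|A∪B| on relative-abundance presence sets.

    When both presence sets are empty the samples are identically empty
    and the distance is defined as 0.
    """
    spec = spec or DistanceSpec(metric="jaccard")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must share one taxon index")
    pa = _presence(a, spec.presence_threshold)
    pb = _presence(b, spec.presence_threshold)
    union = np.logical_or(pa, pb).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(pa, pb).sum()
    return float(1.0 - inter / union)


def pairwise_distances(
    table: CountTable, sample_ids: Sequence[str], spec: Optional[DistanceSpec] = None
) -> pd.DataFrame:
    """Square distance matrix over the given samples."""
    spec = spec or DistanceSpec()
    mat = table.data[list(sample_ids)].to_numpy(dtype=float).T
    n = mat.shape[0]
    if spec.metric == "aitchison":
        clr = clr_transform(mat, spec.pseudocount)
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(clr, metric="euclidean"))
    else:
        dist = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d = jaccard_distance(mat[i], mat[j], spec)
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=list(sample_ids), columns=list(sample_ids))


def participant_dispersion(
    table: CountTable, series: ParticipantSeries, spec: Optional[DistanceSpec] = None
) -> float:
    """Mean pairwise distance over a participant's present samples."""
    spec = spec or DistanceSpec()
    ids = [r.sample_id for r in series.present_records if r.sample_id in table.data.columns]
    if len(ids) < 2:
        raise ValueError(
            f"{series.participant_id}: need >= 2 samples with counts, have {len(ids)}"
        )
    dist = pairwise_distances(table, ids, spec).to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    return float(dist[iu].mean())


def dispersion_by_participant(
    table: CountTable,
    cohort: Iterable[ParticipantSeries],
    spec: Optional[DistanceSpec] = None,
) -> pd.Series:
    """Per-participant total beta-diversity (mean pairwise distance)."""
    out = {
        series.participant_id: participant_dispersion(table, series, spec)
        for series in cohort
    }
    return pd.Series(out, name="dispersion").sort_index()


def event_correlation(
    dispersions: pd.Series, event_counts: pd.Series, method: str = "pearson"
) -> Tuple[float, float]:
    """Correlate per-participant dispersion with per-participant event totals."""
    joined = pd.concat([dispersions, event_counts], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 participants")
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in dispersion or event counts")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def neighbor_distance(
    series: ParticipantSeries, table: CountTable, spec: Optional[DistanceSpec] = None
) -> pd.Series:
    """Mean distance of each sample to its nearest present neighbours.

    Interior samples average the distance to the closest present sample
    before and after (missing days are skipped); the first and last
    samples use their single neighbour.
    """
    spec = spec or DistanceSpec()
    recs = [r for r in series.present_records if r.sample_id in table.data.columns]
    if len(recs) < 2:
        raise ValueError("need >= 2 present samples with counts")
    ids = [r.sample_id for r in recs]
    dist = pairwise_distances(table, ids, spec)
    out = {}
    for i, rec in enumerate(recs):
        neighbours = []
        if i > 0:
            neighbours.append(dist.iloc[i, i - 1])
        if i < len(recs) - 1:
            neighbours.append(dist.iloc[i, i + 1])
        out[rec.sample_id] = float(np.mean(neighbours))
    return pd.Series(out, name="neighbor_distance")


def phage_distance_correlation(
    phage: pd.DataFrame, neighbor_distances: pd.Series, method: str = "spearman"
) -> Tuple[float, float, int]:
    """Spearman correlation of detectable phage ratios with neighbour distance.

    Non-detects carry no rank information and are excluded; the number
    excluded is returned alongside (rho, p).
    """
    if method != "spearman":
        raise ValueError("only spearman is supported")
    detects = phage.loc[~phage["censored"].astype(bool)].set_index("sample_id")["ratio"]
    joined = pd.concat([detects, neighbor_distances], axis=1, join="inner").dropna()
    n_excluded = int(phage["censored"].astype(bool).sum())
    if len(joined) < 3:
        raise ValueError("need >= 3 detectable pairs")
    x = joined.iloc[:, 0].to_numpy()
    y = joined.iloc[:, 1].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in ratios or distances")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p), n_excluded


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j >= i of p_(j) * m / j, clipped at 1, computed as
    the canonical step-up so results are reproducible bit-for-bit.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    qsorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = qsorted
    return q


def prevalence_test(
    table: CountTable,
    group_labels: Mapping[str, bool],
    spec: Optional[DistanceSpec] = None,
    use_exact_fallback: bool = False,
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-taxon 2x2 chi-square of presence between two sample groups.

    ``group_labels`` maps sample id -> True for the first group (e.g.
    menses days). Presence means >= ``presence_threshold`` of the
    sample's reads. Taxa present in all samples or none are degenerate:
    excluded from testing and returned separately. q-values are BH
    across tested taxa; ``low_expected`` flags cells with expected
    count < 5 (optionally retested with Fisher's exact test).
    """
    spec = spec or DistanceSpec()
    samples = [s for s in table.data.columns if s in group_labels]
    if not samples:
        raise ValueError("no samples overlap the group labels")
    in_group = np.array([bool(group_labels[s]) for s in samples])
    if in_group.all() or (~in_group).all():
        raise ValueError("both groups must be non-empty")

    counts = table.data[samples].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = [s for s, t in zip(samples, totals) if t <= 0]
        raise ValueError(f"samples with zero total counts: {bad}")
    presence = (counts / totals) >= spec.presence_threshold

    rows = []
    excluded: List[str] = []
    for taxon, present in zip(table.data.index, presence):
        if present.all() or (~present).all():
            excluded.append(taxon)
            continue
        a = int(np.sum(present & in_group))        # present, group 1
        b = int(np.sum(present & ~in_group))       # present, group 2
        c = int(np.sum(~present & in_group))
        d = int(np.sum(~present & ~in_group))
        contingency = np.array([[a, b], [c, d]])
        chi2, p, _, expected = sps.chi2_contingency(contingency, correction=True)
        low_expected = bool((expected < 5).any())
        if low_expected and use_exact_fallback:
            _, p = sps.fisher_exact(contingency)
            chi2 = float("nan")
        prev1 = a / in_group.sum()
        prev2 = b / (~in_group).sum()
        rows.append(
            {
                "taxon": taxon,
                "chi2": float(chi2),
                "p": float(p),
                "prevalence_group1": prev1,
                "prevalence_group2": prev2,
                "direction": "group1" if prev1 > prev2 else ("group2" if prev2 > prev1 else "equal"),
                "low_expected": low_expected,
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_adjust(result["p"])
    else:
        result["q"] = pd.Series(dtype=float)
    return result, excluded


@dataclasses.dataclass(frozen=True)
class ResampleTestSpec:
    """Parameters of the subsample-then-test rule."""

    m_per_participant: int = 10
    n_trials: int = 10
    alpha: float = 0.05
    min_significant_trials: int = 7
    posthoc: str = "dunn"

    def __post_init__(self) -> None:
        if self.min_significant_trials > self.n_trials:
            raise ValueError("min_significant_trials cannot exceed n_trials")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if self.m_per_participant < 1:
            raise ValueError("m_per_participant must be >= 1")


@dataclasses.dataclass(frozen=True)
class ResampledTestResult:
    """Outcome of the repeated subsampled Kruskal-Wallis rule."""

    trial_pvalues: Tuple[float, ...]
    n_significant: int
    overall_significant: bool
    posthoc: Optional[pd.DataFrame]
    posthoc_on_full_data: bool = True

    def __post_init__(self) -> None:
        if self.overall_significant and self.posthoc is None:
            raise ValueError("significant result requires a post-hoc table")
        if not self.overall_significant and self.posthoc is not None:
            raise ValueError("post-hoc table only accompanies significant results")


def dunn_posthoc(values: np.ndarray, groups: Sequence[str]) -> pd.DataFrame:
    """Dunn's pairwise mean-rank z-tests with tie correction and BH q-values.

    For two groups without ties the statistic coincides with the
    asymptotic Mann-Whitney z (no continuity correction).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n_total = values.size
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    labels = sorted(set(groups.tolist()))
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int(np.sum(groups == g)) for g in labels}

    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": float(z), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out


def resampled_group_test(
    values_by_sample: pd.Series,
    participant_by_sample: pd.Series,
    group_by_participant: Mapping[str, str],
    spec: Optional[ResampleTestSpec] = None,
    seed: int = 0,
) -> ResampledTestResult:
    """Kruskal-Wallis across groups, repeated over participant subsamples.

    Each trial draws at most ``m_per_participant`` samples per
    participant without replacement (participants with fewer contribute
    all of theirs), then tests the subsampled values across groups. The
    rule is significant when p < alpha in at least
    ``min_significant_trials`` of ``n_trials`` trials; the Dunn post-hoc
    is then computed on the full (non-subsampled) data.
    """
    spec = spec or ResampleTestSpec()
    df = pd.DataFrame(
        {
            "value": values_by_sample,
            "participant": participant_by_sample.reindex(values_by_sample.index),
        }
    ).dropna()
    df["group"] = df["participant"].map(dict(group_by_participant))
    df = df.dropna(subset=["group"])

    group_participants = df.groupby("group")["participant"].nunique()
    if len(group_participants) < 2 or (group_participants < 2).any():
        raise ValueError("need >= 2 groups each with >= 2 participants")

    pvalues = []
    for trial in range(spec.n_trials):
        rng = np.random.default_rng([seed, trial])
        picks = []
        for _, sub in df.groupby("participant", sort=True):
            if len(sub) <= spec.m_per_participant:
                picks.append(sub)
            else:
                idx = rng.choice(len(sub), size=spec.m_per_participant, replace=False)
                picks.append(sub.iloc[np.sort(idx)])
        trial_df = pd.concat(picks)
        group_values = [g["value"].to_numpy() for _, g in trial_df.groupby("group", sort=True)]
        if any(len(v) == 0 for v in group_values):
            raise ValueError("a group lost all samples during subsampling")
        _, p = sps.kruskal(*group_values)
        pvalues.append(float(p))

    n_sig = sum(1 for p in pvalues if p < spec.alpha)
    overall = n_sig >= spec.min_significant_trials
    posthoc = (
        dunn_posthoc(df["value"].to_numpy(), df["group"].to_numpy()) if overall else None
    )
    return ResampledTestResult(
        trial_pvalues=tuple(pvalues),
        n_significant=n_sig,
        overall_significant=overall,
        posthoc=posthoc,
    )
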