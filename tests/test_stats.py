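"""Compositional distances, correlations, prevalence and resampled tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from vcdkit.simulate import (
    CalendarParams,
    CompositionModel,
    PhageModel,
    RegimeParams,
    simulate_calendar,
    simulate_composition,
    simulate_trajectory,
)
from vcdkit.stats import (
    DistanceSpec,
    ResampleTestSpec,
    aitchison_distance,
    bh_adjust,
    clr_transform,
    dispersion_by_participant,
    dunn_posthoc,
    event_correlation,
    jaccard_distance,
    neighbor_distance,
    participant_dispersion,
    phage_distance_correlation,
    prevalence_test,
    resampled_group_test,
)
from vcdkit.types import CountTable

from conftest import make_series

positive_vectors = st.lists(
    st.floats(min_value=0.5, max_value=1e4), min_size=3, max_size=12
)


def bh_stepup_oracle(pvalues):
    """Textbook BH step-up, written independently of the implementation."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


class TestClr:
    def test_uniform_vector_maps_to_zero(self):
        assert np.allclose(clr_transform(np.array([1, 1, 1, 1]), 1.0), 0.0)

    def test_two_part_closed_form(self):
        out = clr_transform(np.array([8.0, 2.0]), 0.0)
        assert np.allclose(out, [np.log(2), -np.log(2)])

    @given(vec=positive_vectors)
    def test_output_sums_to_zero(self, vec):
        assert abs(clr_transform(np.array(vec), 1.0).sum()) < 1e-9

    def test_zero_counts_need_pseudocount(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([0.0, 1.0]), 0.0)


class TestAitchison:
    def test_identical_columns_distance_zero(self):
        x = np.array([3.0, 5.0, 2.0])
        assert aitchison_distance(x, x) == 0.0

    def test_scale_invariance_without_pseudocount(self):
        spec = DistanceSpec(pseudocount=0.0)
        x = np.array([8.0, 2.0, 5.0])
        assert aitchison_distance(x, 2 * x, spec) < 1e-12

    def test_two_part_hand_computation(self):
        spec = DistanceSpec(pseudocount=0.0)
        d = aitchison_distance(np.array([8.0, 2.0]), np.array([2.0, 8.0]), spec)
        assert abs(d - 2 * np.sqrt(2) * np.log(2)) < 1e-12

    @given(
        a=positive_vectors.filter(lambda v: len(v) >= 4),
        b=positive_vectors.filter(lambda v: len(v) >= 4),
        c=positive_vectors.filter(lambda v: len(v) >= 4),
    )
    def test_metric_axioms_on_random_triples(self, a, b, c):
        n = min(len(a), len(b), len(c))
        a, b, c = (np.array(v[:n]) for v in (a, b, c))
        spec = DistanceSpec(pseudocount=0.0)
        dab = aitchison_distance(a, b, spec)
        assert abs(dab - aitchison_distance(b, a, spec)) < 1e-9
        assert dab + aitchison_distance(b, c, spec) >= aitchison_distance(a, c, spec) - 1e-9

    def test_matches_skbio_oracle(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(12)
        for _ in range(50):
            a = rng.uniform(0.5, 100.0, size=10)
            b = rng.uniform(0.5, 100.0, size=10)
            expected = float(
                np.linalg.norm(skbio_comp.clr(a / a.sum()) - skbio_comp.clr(b / b.sum()))
            )
            got = aitchison_distance(a, b, DistanceSpec(pseudocount=0.0))
            assert abs(got - expected) < 1e-10


class TestJaccard:
    def test_identical_presence_sets(self):
        spec = DistanceSpec(metric="jaccard", presence_threshold=0.005)
        a = np.array([100.0, 50.0, 0.0])
        assert jaccard_distance(a, 2 * a, spec) == 0.0

    def test_disjoint_sets(self):
        a = np.array([100.0, 0.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 50.0, 50.0])
        assert jaccard_distance(a, b) == 1.0

    def test_partial_overlap_two_thirds(self):
        a = np.array([50.0, 50.0, 0.0])
        b = np.array([50.0, 0.0, 50.0])
        assert abs(jaccard_distance(a, b) - 2 / 3) < 1e-12

    def test_threshold_is_relative_so_depth_invariant(self):
        spec = DistanceSpec(metric="jaccard", presence_threshold=0.01)
        a = np.array([99.0, 1.0, 0.5])
        b = np.array([90.0, 10.0, 0.0])
        assert jaccard_distance(a, b, spec) == jaccard_distance(a * 7, b * 13, spec)

    def test_both_empty_sets_defined_as_zero(self):
        a = np.zeros(3)
        assert jaccard_distance(a, a) == 0.0


def _toy_table(columns):
    return CountTable(pd.DataFrame(columns))


class TestDispersion:
    def _series_with_samples(self, pid, n):
        return make_series(pid, lambda d: "I", missing_days=set(range(4 + n, 33)))

    def test_two_identical_samples_zero(self):
        series = self._series_with_samples("P", 2)
        table = _toy_table({"P_d04": [5, 5, 1], "P_d05": [5, 5, 1]})
        assert participant_dispersion(table, series) == 0.0

    def test_three_samples_mean_of_pairwise(self):
        series = self._series_with_samples("P", 3)
        cols = {
            "P_d04": [8.0, 2.0, 1.0],
            "P_d05": [2.0, 8.0, 1.0],
            "P_d06": [1.0, 1.0, 8.0],
        }
        table = _toy_table(cols)
        spec = DistanceSpec(pseudocount=0.0)
        vals = {k: np.array(v) for k, v in cols.items()}
        expected = np.mean(
            [
                aitchison_distance(vals["P_d04"], vals["P_d05"], spec),
                aitchison_distance(vals["P_d04"], vals["P_d06"], spec),
                aitchison_distance(vals["P_d05"], vals["P_d06"], spec),
            ]
        )
        assert abs(participant_dispersion(table, series, spec) - expected) < 1e-12

    def test_depth_rescaling_leaves_aitchison_dispersion(self):
        series = self._series_with_samples("P", 3)
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 50, size=(4, 3))
        cols = {f"P_d0{4+i}": base[:, i] for i in range(3)}
        scaled = {k: v * (10 + i) for i, (k, v) in enumerate(cols.items())}
        spec = DistanceSpec(pseudocount=0.0)
        d1 = participant_dispersion(_toy_table(cols), series, spec)
        d2 = participant_dispersion(_toy_table(scaled), series, spec)
        assert abs(d1 - d2) < 1e-9

    def test_single_sample_rejected(self):
        series = self._series_with_samples("P", 1)
        table = _toy_table({"P_d04": [1, 2, 3]})
        with pytest.raises(ValueError, match=">= 2"):
            participant_dispersion(table, series)


class TestEventCorrelation:
    def test_proportional_events_r_one(self):
        disp = pd.Series({"P1": 0.1, "P2": 0.2, "P3": 0.3, "P4": 0.4})
        events = pd.Series({"P1": 1, "P2": 2, "P3": 3, "P4": 4})
        r, p = event_correlation(disp, events)
        assert abs(r - 1.0) < 1e-12

    def test_zero_variance_rejected(self):
        disp = pd.Series({"P1": 0.5, "P2": 0.5, "P3": 0.5})
        events = pd.Series({"P1": 1, "P2": 2, "P3": 3})
        with pytest.raises(ValueError, match="variance"):
            event_correlation(disp, events)

    def test_intercourse_triggered_switching_gives_positive_r(self):
        """Participants with more intercourse accumulate more quantitative change."""
        regime = RegimeParams(
            regime="unstable",
            p_dysbiosis_menses=0.0,
            p_dysbiosis_spont=0.0,
            p_dysbiosis_intercourse=0.9,
            p_recover=0.5,
        )
        cohort, tables = [], []
        for i, rate in enumerate([0.0, 0.05, 0.15, 0.3, 0.5, 0.7]):
            params = CalendarParams(missingness_rate=0.0, intercourse_rate=rate)
            cal = simulate_calendar(params, seed=100 + i)
            series = simulate_trajectory(cal, regime, seed=200 + i, participant_id=f"P{i}")
            cohort.append(series)
            tables.append(simulate_composition(series, CompositionModel(), seed=300 + i).data)
        table = CountTable(pd.concat(tables, axis=1))
        disp = dispersion_by_participant(table, cohort)
        totals = pd.Series(
            {s.participant_id: sum(r.intercourse for r in s.records) for s in cohort}
        )
        r, _ = event_correlation(disp, totals)
        assert r > 0.5


class TestNeighborDistance:
    def test_constant_composition_all_zero(self):
        series = make_series("P", lambda d: "I", missing_days=set(range(8, 33)))
        table = _toy_table({f"P_d0{d}": [5, 3, 2] for d in range(4, 8)})
        out = neighbor_distance(series, table)
        assert (out == 0.0).all()

    def test_outlier_day_has_strictly_largest_neighbor_distance(self):
        series = make_series("P", lambda d: "I", missing_days=set(range(9, 33)))
        base = [10.0, 1.0, 1.0]
        cols = {f"P_d0{d}": list(base) for d in (4, 5, 7, 8)}
        cols["P_d06"] = [1.0, 10.0, 1.0]
        table = _toy_table(cols)
        out = neighbor_distance(series, table, DistanceSpec(pseudocount=0.0))
        assert out.idxmax() == "P_d06"
        assert (out.drop("P_d06") < out["P_d06"]).all()

    def test_missing_day_skips_to_nearest_present(self):
        series = make_series(
            "P", lambda d: "I", missing_days={5} | set(range(7, 33))
        )
        table = _toy_table({"P_d04": [8.0, 2.0], "P_d06": [2.0, 8.0]})
        spec = DistanceSpec(pseudocount=0.0)
        out = neighbor_distance(series, table, spec)
        expected = aitchison_distance(np.array([8.0, 2.0]), np.array([2.0, 8.0]), spec)
        assert abs(out["P_d04"] - expected) < 1e-12
        assert abs(out["P_d06"] - expected) < 1e-12


class TestPhageCorrelation:
    def test_monotone_pairs_rho_one(self):
        phage = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(6)],
                "ratio": [1e-4 * (i + 1) for i in range(6)],
                "censored": [False] * 6,
            }
        )
        neigh = pd.Series({f"S{i}": 0.1 * (i + 1) for i in range(6)})
        rho, p, n_exc = phage_distance_correlation(phage, neigh)
        assert rho == 1.0
        assert n_exc == 0

    def test_nondetects_excluded_and_counted(self):
        phage = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(8)],
                "ratio": [0.0, 0.0] + [1e-4 * i for i in range(1, 7)],
                "censored": [True, True] + [False] * 6,
            }
        )
        neigh = pd.Series({f"S{i}": 0.1 * (i + 1) for i in range(8)})
        rho, _, n_exc = phage_distance_correlation(phage, neigh)
        assert n_exc == 2
        assert rho == 1.0

    def test_null_pairs_have_small_rho(self):
        rng = np.random.default_rng(5)
        ids = [f"S{i}" for i in range(500)]
        phage = pd.DataFrame(
            {"sample_id": ids, "ratio": rng.lognormal(-9, 1, 500), "censored": False}
        )
        neigh = pd.Series(rng.uniform(0, 1, 500), index=ids)
        rho, p, _ = phage_distance_correlation(phage, neigh)
        assert abs(rho) < 0.1

    def test_constant_ratios_rejected(self):
        phage = pd.DataFrame(
            {"sample_id": ["S1", "S2", "S3"], "ratio": [1e-4] * 3, "censored": False}
        )
        neigh = pd.Series({"S1": 0.1, "S2": 0.2, "S3": 0.3})
        with pytest.raises(ValueError, match="variance"):
            phage_distance_correlation(phage, neigh)


class TestPrevalence:
    def _table(self, n_per_group=20):
        cols = {}
        for i in range(n_per_group):
            cols[f"M{i}"] = [500, 400, 100, 10]   # menses: taxon A present
            cols[f"N{i}"] = [0, 400, 100, 10]     # non-menses: taxon A absent
        return CountTable(pd.DataFrame(cols, index=["A", "B", "C", "D"]).astype(float))

    def _labels(self, n_per_group=20):
        labels = {f"M{i}": True for i in range(n_per_group)}
        labels.update({f"N{i}": False for i in range(n_per_group)})
        return labels

    def test_perfectly_separated_taxon_is_significant(self):
        result, excluded = prevalence_test(self._table(), self._labels())
        row = result.set_index("taxon").loc["A"]
        assert row["q"] < 1e-6
        assert row["direction"] == "group1"
        # taxa B, C, D are present everywhere -> degenerate, excluded
        assert set(excluded) == {"B", "C", "D"}

    def test_equal_prevalence_p_one(self):
        cols = {}
        for i in range(10):
            cols[f"M{i}"] = [100 if i % 2 else 0, 100]
            cols[f"N{i}"] = [100 if i % 2 else 0, 100]
        table = CountTable(pd.DataFrame(cols, index=["A", "B"]).astype(float))
        result, _ = prevalence_test(table, self._labels(10))
        assert result.set_index("taxon").loc["A", "p"] == 1.0

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            prevalence_test(self._table(), {f"M{i}": True for i in range(20)})


class TestBenjaminiHochberg:
    @given(
        pvals=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_independent_stepup_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_stepup_oracle(pvals), atol=0.0)

    def test_agrees_with_statsmodels_to_rounding(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 50)))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, rtol=1e-12, atol=0)

    def test_qvalues_monotone_in_sorted_pvalues(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestDunn:
    def test_two_groups_match_mannwhitney_asymptotics(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0.8, 1, 15)
            values = np.concatenate([x, y])
            groups = ["a"] * 12 + ["b"] * 15
            out = dunn_posthoc(values, groups).iloc[0]
            ref = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            assert abs(out["p"] - ref.pvalue) < 1e-12

    def test_three_groups_pairs_and_bh(self):
        rng = np.random.default_rng(9)
        values = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(3, 1, 10)]
        )
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        out = dunn_posthoc(values, groups)
        assert len(out) == 3
        by_pair = out.set_index(["group1", "group2"])
        assert by_pair.loc[("a", "c"), "p"] < 0.01
        assert by_pair.loc[("a", "b"), "p"] > 0.05
        assert np.allclose(out["q"], bh_stepup_oracle(out["p"]))


def _grouped_values(rng, n_participants, samples_each, shift=0.0, group="g"):
    values, participants = [], []
    for i in range(n_participants):
        pid = f"{group}{i}"
        values.extend(rng.normal(shift, 1.0, samples_each))
        participants.extend([pid] * samples_each)
    return values, participants


class TestResampledGroupTest:
    def _inputs(self, shift, seed=0, n_part=8, samples_each=26):
        rng = np.random.default_rng(seed)
        va, pa = _grouped_values(rng, n_part, samples_each, 0.0, "a")
        vb, pb = _grouped_values(rng, n_part, samples_each, shift, "b")
        idx = [f"S{i}" for i in range(len(va) + len(vb))]
        values = pd.Series(va + vb, index=idx)
        participants = pd.Series(pa + pb, index=idx)
        groups = {f"a{i}": "A" for i in range(n_part)}
        groups.update({f"b{i}": "B" for i in range(n_part)})
        return values, participants, groups

    def test_strongly_separated_groups_all_trials_significant(self):
        values, participants, groups = self._inputs(shift=10.0)
        result = resampled_group_test(values, participants, groups, seed=1)
        assert result.n_significant == 10
        assert result.overall_significant
        assert result.posthoc is not None and len(result.posthoc) == 1

    def test_m_above_sample_counts_degenerates_to_full_test(self):
        values, participants, groups = self._inputs(shift=0.5, samples_each=6)
        spec = ResampleTestSpec(m_per_participant=50)
        result = resampled_group_test(values, participants, groups, spec, seed=2)
        assert len(set(result.trial_pvalues)) == 1
        grp = participants.map(groups)
        _, p_full = sps.kruskal(
            values[grp == "A"].to_numpy(), values[grp == "B"].to_numpy()
        )
        assert abs(result.trial_pvalues[0] - p_full) < 1e-12

    def test_same_seed_bit_reproducible(self):
        values, participants, groups = self._inputs(shift=0.3)
        r1 = resampled_group_test(values, participants, groups, seed=7)
        r2 = resampled_group_test(values, participants, groups, seed=7)
        assert r1.trial_pvalues == r2.trial_pvalues

    def test_too_few_participants_rejected(self):
        values = pd.Series([1.0, 2.0], index=["S1", "S2"])
        participants = pd.Series(["a0", "b0"], index=["S1", "S2"])
        with pytest.raises(ValueError, match="participants"):
            resampled_group_test(values, participants, {"a0": "A", "b0": "B"})
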