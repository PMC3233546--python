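"""Marker-selection cascade: stage rules, ranking, and brute-force parity."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from methylscreen.cohort import CohortValidationError
from methylscreen.select import (
    MarkerSelector,
    average_replicates,
    drop_annotated_probes,
    drop_failed_probes,
    drop_pbl_methylated,
    rank_by_separation,
    run_selection,
    select_top_markers,
    summarize_group_distributions,
)
from methylscreen.simulate import SimConfig, generate_infinium_cohort

from conftest import make_annotation, make_cohort


class TestDetectionQC:
    def test_all_pass_is_identity(self):
        cohort = make_cohort({"p1": [0.1, 0.2, 0.0, 0.0], "p2": [0.5, 0.6, 0.1, 0.1]})
        out, report = drop_failed_probes(cohort)
        assert list(out.probe_ids) == ["p1", "p2"]
        assert report.removed_probe_ids == []

    def test_single_failure_in_any_sample_removes_probe(self):
        # one failed measurement anywhere disqualifies the whole probe
        detp = {"p1": [0.0, 0.06, 0.0, 0.0], "p2": [0.0, 0.05, 0.0, 0.0]}
        beta = {"p1": [0.5] * 4, "p2": [0.5] * 4}
        out, report = drop_failed_probes(make_cohort(beta, detp))
        assert report.removed_probe_ids == ["p1"]  # 0.05 itself passes (> rule)
        assert list(out.probe_ids) == ["p2"]

    def test_engineered_failures_match_exhaustive_scan(self, rng):
        n_probes, n_samples = 10, 6
        detp_mat = rng.uniform(0, 0.05, size=(n_probes, n_samples))
        fail_at = [(0, 3), (4, 0), (7, 5)]
        for r, c in fail_at:
            detp_mat[r, c] = 0.5
        probes = [f"p{i}" for i in range(n_probes)]
        beta = {p: list(rng.uniform(0, 1, n_samples)) for p in probes}
        detp = {p: list(detp_mat[i]) for i, p in enumerate(probes)}
        cohort = make_cohort(beta, detp,
                             tumor_cols=["T1", "T2", "T3", "T4"],
                             pbl_cols=["B1", "B2"])
        out, report = drop_failed_probes(cohort)
        # independent brute-force scan over every cell
        expected_removed = sorted(
            {probes[r] for r in range(n_probes) for c in range(n_samples)
             if detp_mat[r, c] > 0.05}
        )
        assert sorted(report.removed_probe_ids) == expected_removed
        assert set(out.probe_ids) == set(probes) - set(expected_removed)


class TestAnnotationFilter:
    def test_no_flags_is_identity(self):
        cohort = make_cohort({"p1": [0.1] * 4, "p2": [0.2] * 4})
        ann = make_annotation(["p1", "p2"])
        out, report = drop_annotated_probes(cohort, ann)
        assert list(out.probe_ids) == ["p1", "p2"]

    def test_snp_or_repeat_union(self):
        probes = [f"p{i}" for i in range(20)]
        cohort = make_cohort({p: [0.1] * 4 for p in probes})
        snp = {"p0", "p1", "p2", "p3", "p19"}   # p19 also repeat-flagged
        repeat = {"p10", "p11", "p12", "p19"}
        ann = make_annotation(probes, snp=snp, repeat=repeat)
        out, report = drop_annotated_probes(cohort, ann)
        assert set(report.removed_probe_ids) == snp | repeat  # 8 distinct
        assert len(report.removed_probe_ids) == 8

    def test_unannotated_probe_is_an_error(self):
        cohort = make_cohort({"p1": [0.1] * 4, "p2": [0.1] * 4})
        ann = make_annotation(["p1"])
        with pytest.raises(CohortValidationError, match="annotation"):
            drop_annotated_probes(cohort, ann)


class TestReplicateAveraging:
    def test_two_subjects_two_replicates(self):
        cohort = make_cohort(
            {"p1": [0.5, 0.10, 0.30, 0.40, 0.60], "p2": [0.9, 0.0, 0.2, 1.0, 0.8]},
            tumor_cols=["T1"],
            pbl_cols=["B1a", "B1b", "B2a", "B2b"],
            replicate_map={"B1a": "B1", "B1b": "B1", "B2a": "B2", "B2b": "B2"},
        )
        out = average_replicates(cohort)
        assert out.pbl_samples == ["B1", "B2"]
        assert out.beta.loc["p1", "B1"] == pytest.approx(0.20)
        assert out.beta.loc["p1", "B2"] == pytest.approx(0.50)
        assert out.beta.loc["p2", "B1"] == pytest.approx(0.10)
        assert out.beta.loc["p2", "B2"] == pytest.approx(0.90)
        # tumors untouched
        assert out.beta.loc["p1", "T1"] == 0.5

    def test_detection_p_collapses_conservatively(self):
        cohort = make_cohort(
            {"p1": [0.5, 0.1, 0.3]},
            detection_p={"p1": [0.0, 0.01, 0.04]},
            tumor_cols=["T1"], pbl_cols=["B1a", "B1b"],
            replicate_map={"B1a": "B1", "B1b": "B1"},
        )
        out = average_replicates(cohort)
        assert out.detection_p.loc["p1", "B1"] == pytest.approx(0.04)  # max, not mean

    def test_subject_spanning_groups_is_an_error(self):
        cohort = make_cohort(
            {"p1": [0.5, 0.1, 0.3]},
            tumor_cols=["T1"], pbl_cols=["B1a", "B1b"],
            replicate_map={"B1a": "T1", "B1b": "B1"},
        )
        with pytest.raises(CohortValidationError, match="span"):
            average_replicates(cohort)


class TestPblFilter:
    def test_boundary_is_inclusive(self):
        # a probe sitting exactly at the threshold is excluded (>= rule)
        cohort = make_cohort(
            {"at": [0.9, 0.20, 0.0], "below": [0.9, 0.19999, 0.0]},
            tumor_cols=["T1"], pbl_cols=["B1", "B2"],
        )
        out, report = drop_pbl_methylated(cohort, threshold=0.2)
        assert report.removed_probe_ids == ["at"]
        assert list(out.probe_ids) == ["below"]

    def test_any_subject_rule(self):
        cohort = make_cohort(
            {"p1": [0.9, 0.19, 0.21]}, tumor_cols=["T1"], pbl_cols=["B1", "B2"]
        )
        _, report = drop_pbl_methylated(cohort)
        assert report.removed_probe_ids == ["p1"]

    def test_no_pbl_samples_is_an_error(self):
        cohort = make_cohort({"p1": [0.5, 0.6]}, tumor_cols=["T1", "T2"], pbl_cols=[])
        with pytest.raises(CohortValidationError, match="PBL"):
            drop_pbl_methylated(cohort)


class TestSeparationRanking:
    def test_zero_delta_dropped(self):
        cohort = make_cohort({"p1": [0.0, 0.0, 0.0, 0.0]})
        assert rank_by_separation(cohort) == []

    def test_hand_enumerated_ordering(self):
        cohort = make_cohort(
            {
                "A": [0.5, 0.6, 0.7, 0.10, 0.15],
                "B": [0.3, 0.2, 0.9, 0.25, 0.10],
                "C": [0.05, 0.06, 0.07, 0.01, 0.02],
            },
            tumor_cols=["T1", "T2", "T3"], pbl_cols=["B1", "B2"],
        )
        ranked = rank_by_separation(cohort)
        assert [m.probe_id for m in ranked] == ["A", "C"]
        assert ranked[0].delta == pytest.approx(0.35)
        assert ranked[0].t_low == pytest.approx(0.5)
        assert ranked[0].pbl_high == pytest.approx(0.15)
        assert ranked[1].delta == pytest.approx(0.03)
        assert [m.rank for m in ranked] == [1, 2]

    def test_ties_broken_by_probe_id(self):
        cohort = make_cohort(
            {"z": [0.5, 0.1, 0.1], "a": [0.5, 0.1, 0.1]},
            tumor_cols=["T1"], pbl_cols=["B1", "B2"],
        )
        ranked = rank_by_separation(cohort)
        assert [m.probe_id for m in ranked] == ["a", "z"]

    def test_missing_tumor_beta_is_an_error(self):
        cohort = make_cohort({"p1": [np.nan, 0.2, 0.1, 0.0]},
                             tumor_cols=["T1", "T2"], pbl_cols=["B1", "B2"])
        with pytest.raises(CohortValidationError, match="missing"):
            rank_by_separation(cohort)


class TestTopMarkers:
    def _ranked(self, genes):
        from methylscreen.select import RankedMarker

        return [
            RankedMarker(probe_id=f"p{i}", gene_symbol=g, t_low=0.5, pbl_high=0.1,
                         delta=0.4 - i * 0.01, rank=i + 1)
            for i, g in enumerate(genes)
        ]

    def test_k_beyond_length_returns_all(self):
        ranked = self._ranked(["g1", "g2"])
        assert select_top_markers(ranked, k=10) == ranked

    def test_truncates_to_k(self):
        ranked = self._ranked([f"g{i}" for i in range(30)])
        assert len(select_top_markers(ranked, k=15)) == 15

    def test_unique_genes_skips_duplicate_then_continues(self):
        ranked = self._ranked(["shared", "shared", "other"])
        top = select_top_markers(ranked, k=2, unique_genes=True)
        assert [m.rank for m in top] == [1, 3]


class TestGroupSummaries:
    def test_even_n_median(self):
        cohort = make_cohort(
            {"p1": [0.1, 0.2, 0.3, 0.4, 0.0, 0.0]},
            tumor_cols=["T1", "T2", "T3", "T4"], pbl_cols=["B1", "B2"],
        )
        df = summarize_group_distributions({"c": cohort}, ["p1"])
        med = df[(df.group == "tumor")]["median"].iloc[0]
        assert med == pytest.approx(0.25)

    def test_missing_marker_recorded_not_raised(self):
        cohort = make_cohort({"p1": [0.1, 0.2, 0.0, 0.0]})
        df = summarize_group_distributions({"c": cohort}, ["absent"])
        assert (df.n == 0).all()

    def test_two_cohorts_from_one_distribution_agree(self):
        cfg_a = SimConfig(n_probes=300, n_planted_markers=20, seed=11)
        cfg_b = SimConfig(n_probes=300, n_planted_markers=20, seed=12)
        ca, _, ta = generate_infinium_cohort(cfg_a)
        cb, _, tb = generate_infinium_cohort(cfg_b)
        # planted probes share an id space position-wise only by chance;
        # compare the distribution of per-marker tumor medians instead
        da = summarize_group_distributions({"a": ca}, ta.planted_probe_ids)
        db = summarize_group_distributions({"b": cb}, tb.planted_probe_ids)
        med_a = da[da.group == "tumor"]["median"]
        med_b = db[db.group == "tumor"]["median"]
        se = np.sqrt(med_a.var() / len(med_a) + med_b.var() / len(med_b))
        assert abs(med_a.mean() - med_b.mean()) < 3 * se


def brute_force_cascade(cohort, ann, alpha=0.05, pbl_threshold=0.2):
    """Independent reimplementation by explicit loops over cells."""
    survivors = []
    tumors = cohort.tumor_samples
    pbls = cohort.pbl_samples
    subjects = sorted(set(cohort.replicate_of.loc[pbls]),
                      key=list(cohort.replicate_of.loc[pbls]).index)
    for p in cohort.probe_ids:
        if any(cohort.detection_p.loc[p, s] > alpha for s in cohort.sample_ids):
            continue
        if ann.table.loc[p, "snp_flag"] or ann.table.loc[p, "repeat_flag"]:
            continue
        avg = {}
        for subj in subjects:
            reps = [s for s in pbls if cohort.replicate_of.loc[s] == subj]
            avg[subj] = sum(cohort.beta.loc[p, s] for s in reps) / len(reps)
        if any(v >= pbl_threshold for v in avg.values()):
            continue
        t_low = min(cohort.beta.loc[p, t] for t in tumors)
        pbl_high = max(avg.values())
        delta = t_low - pbl_high
        if delta <= 0:
            continue
        survivors.append((p, delta))
    survivors.sort(key=lambda x: (-x[1], x[0]))
    return survivors


class TestCascadeProperties:
    def test_matches_brute_force_on_small_cohorts(self):
        for seed in range(5):
            cfg = SimConfig(n_probes=50, n_tumors=5, n_planted_markers=8,
                            fail_fraction=0.02, seed=seed)
            cohort, ann, _ = generate_infinium_cohort(cfg)
            ranked, _, reports = run_selection(cohort, ann, top_k=50)
            expected = brute_force_cascade(cohort, ann)
            assert [(m.probe_id, m.delta) for m in ranked] == pytest.approx(expected)
            # funnel reconciles end to end
            for prev, nxt in zip(reports, reports[1:]):
                assert nxt.probes_in == prev.probes_out

    def test_sample_column_permutation_invariance(self):
        cfg = SimConfig(n_probes=60, n_tumors=6, n_planted_markers=10, seed=3)
        cohort, ann, _ = generate_infinium_cohort(cfg)
        ranked1, _, _ = run_selection(cohort, ann)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cohort.sample_ids))
        shuffled = type(cohort)(
            beta=cohort.beta.iloc[:, perm],
            detection_p=cohort.detection_p.iloc[:, perm],
            groups=cohort.groups,
            replicate_of=cohort.replicate_of,
        )
        ranked2, _, _ = run_selection(shuffled, ann)
        assert [(m.probe_id, m.delta) for m in ranked1] == [
            (m.probe_id, m.delta) for m in ranked2
        ]

    def test_retained_markers_strictly_separate(self):
        cfg = SimConfig(n_probes=200, n_planted_markers=20, seed=7)
        cohort, ann, _ = generate_infinium_cohort(cfg)
        ranked, _, _ = run_selection(cohort, ann, top_k=200)
        assert all(m.t_low > m.pbl_high for m in ranked)
        assert all(m.delta == pytest.approx(m.t_low - m.pbl_high) for m in ranked)

    def test_planted_recovery_and_pbl_high_exclusion(self):
        # planted recall 1.0 and no leukocyte-methylated probe survives
        for seed in range(20):
            cfg = SimConfig(n_probes=300, n_planted_markers=15, seed=seed)
            cohort, ann, truth = generate_infinium_cohort(cfg)
            ranked, _, _ = run_selection(cohort, ann, top_k=300)
            retained = {m.probe_id for m in ranked}
            assert set(truth.planted_probe_ids) <= retained
            assert not (set(truth.pbl_high_probe_ids) & retained)


class TestMarkerSelectorEstimator:
    def _fit_inputs(self, seed=5):
        cfg = SimConfig(n_probes=120, n_tumors=8, n_planted_markers=10, seed=seed)
        cohort, ann, truth = generate_infinium_cohort(cfg)
        X = cohort.beta.T  # samples × probes
        y = [cohort.groups.loc[s] for s in X.index]
        return X, y, cohort, ann, truth

    def test_fit_transform_selects_planted_markers(self):
        X, y, cohort, ann, truth = self._fit_inputs()
        sel = MarkerSelector(top_k=10)
        sel.fit(X, y, detection_p=cohort.detection_p,
                annotation=ann, replicate_of=cohort.replicate_of)
        Xt = sel.transform(X)
        assert Xt.shape == (X.shape[0], 10)
        assert set(Xt.columns) <= set(truth.planted_probe_ids)
        assert sel.get_support().sum() == 10

    def test_sklearn_param_interface(self):
        sel = MarkerSelector(top_k=7, pbl_threshold=0.3)
        params = sel.get_params()
        assert params["top_k"] == 7 and params["pbl_threshold"] == 0.3
        cloned = clone(sel)
        assert cloned.get_params() == params

    def test_matches_functional_cascade(self):
        X, y, cohort, ann, _ = self._fit_inputs(seed=9)
        sel = MarkerSelector(top_k=5).fit(
            X, y, detection_p=cohort.detection_p, annotation=ann,
            replicate_of=cohort.replicate_of,
        )
        _, top, _ = run_selection(cohort, ann, top_k=5)
        assert [m.probe_id for m in sel.selected_markers_] == [
            m.probe_id for m in top
        ]
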