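"""Arm-level screening, i(17q), R^2 selection and successive stratification."""

import numpy as np
import pandas as pd
import pytest

from survsig.cna import (
    derive_i17q,
    screen_aberrations,
    select_by_r2,
    successive_stratify,
)
from survsig.signature import core_average_score
from survsig.synthetic import nested_arm_config, simulate_cohort
from tests.conftest import collapse_trivially


def make_samples(n, times, events):
    return pd.DataFrame(
        {"os_years": times, "os_event": events},
        index=[f"s{i}" for i in range(n)])


def make_calls(n, **columns):
    return pd.DataFrame(columns, index=[f"s{i}" for i in range(n)])


class TestDeriveI17q:
    @pytest.mark.parametrize(
        "p17, q17, expected",
        [(-1, 1, True), (-1, 0, False), (0, 1, False), (1, -1, False)],
    )
    def test_truth_table(self, p17, q17, expected):
        calls = make_calls(1, **{"17p": [p17], "17q": [q17]})
        assert derive_i17q(calls).iloc[0] == expected

    def test_missing_arm_rejected(self):
        with pytest.raises(ValueError, match="17q"):
            derive_i17q(make_calls(1, **{"17p": [-1]}))

    def test_subset_of_intersection(self, nested_bundle):
        calls = nested_bundle.arm_calls.copy()
        calls["17p"] = calls["8q"]
        calls["17q"] = -calls["9p"]
        ind = derive_i17q(calls)
        assert (ind <= ((calls["17p"] == -1) & (calls["17q"] == 1))).all()


class TestScreenAberrations:
    def test_low_frequency_arm_not_tested(self):
        rng = np.random.default_rng(0)
        n = 200
        t = rng.exponential(1, n)
        e = np.ones(n, int)
        rare = np.zeros(n, int)
        rare[:18] = 1  # 9% carriers
        common = np.zeros(n, int)
        common[:40] = -1
        calls = make_calls(n, rare=rare, common=common)
        samples = make_samples(n, t, e)
        events = screen_aberrations(calls, samples, min_freq=0.10)
        labels = [ev.label for ev in events]
        assert "rare_gain" not in labels
        assert "common_loss" in labels

    def test_protective_designation_by_hr_direction(self):
        rng = np.random.default_rng(1)
        n = 300
        carrier = (rng.random(n) < 0.4).astype(int)
        t = rng.exponential(np.exp(-np.log(0.4) * carrier), n)
        samples = make_samples(n, t, np.ones(n, int))
        events = screen_aberrations(make_calls(n, a=carrier), samples)
        ev = [e for e in events if e.label == "a_gain"][0]
        assert ev.designation == "protective"
        assert ev.cox.hr_per_unit[0] < 1

    def test_sample_order_invariance(self, nested_bundle):
        s = nested_bundle.samples
        calls = nested_bundle.arm_calls
        e1 = screen_aberrations(calls, s)
        perm = s.sample(frac=1.0, random_state=3)
        e2 = screen_aberrations(calls, perm)
        assert [(e.label, round(e.p, 12)) for e in e1] == \
            [(e.label, round(e.p, 12)) for e in e2]

    def test_planted_protective_arm_detected(self):
        hits = 0
        for seed in range(10):
            b = simulate_cohort(nested_arm_config(seed))
            events = screen_aberrations(b.arm_calls, b.samples)
            det = {e.label: e.designation for e in events}
            hits += det.get("8q_loss") == "protective"
        assert hits >= 9


class TestSelectByR2:
    def _screened(self, calls, samples):
        return screen_aberrations(calls, samples, min_freq=0.05, alpha=1.1)

    def test_collinear_candidate_dropped(self):
        rng = np.random.default_rng(2)
        n = 120
        x = (rng.random(n) < 0.3).astype(int)
        t = rng.exponential(np.exp(-0.8 * x), n)
        calls = make_calls(n, a=x, b=x)  # identical indicator vectors
        samples = make_samples(n, t, np.ones(n, int))
        selected, trace = select_by_r2(self._screened(calls, samples), samples)
        decisions = dict(zip(trace["event"], trace["decision"]))
        kept = [e.label for e in selected]
        assert len([k for k in kept if k.endswith("_gain")]) == 1
        assert "collinear" in decisions.values()

    def test_small_increment_rejected(self):
        rng = np.random.default_rng(3)
        n = 150
        strong = (rng.random(n) < 0.4).astype(int)
        noise = (rng.random(n) < 0.3).astype(int)
        t = rng.exponential(np.exp(-1.0 * strong), n)
        calls = make_calls(n, strong=strong, noise=noise)
        samples = make_samples(n, t, np.ones(n, int))
        selected, trace = select_by_r2(
            self._screened(calls, samples), samples, delta_r2_min=0.01)
        kept = [e.label for e in selected]
        assert "strong_gain" in kept
        assert "noise_gain" not in kept

    def test_true_arm_selected_before_correlated_passenger(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 250
            true = (rng.random(n) < 0.35).astype(int)
            # passenger co-occurs with the true arm but adds no effect
            passenger = np.where(true == 1, (rng.random(n) < 0.7),
                                 (rng.random(n) < 0.1)).astype(int)
            t = rng.exponential(np.exp(-0.9 * true), n)
            calls = make_calls(n, true=true, passenger=passenger)
            samples = make_samples(n, t, np.ones(n, int))
            selected, _ = select_by_r2(self._screened(calls, samples), samples)
            if selected and selected[0].label == "true_gain":
                wins += 1
        assert wins >= 16

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_by_r2([], make_samples(2, [1.0, 2.0], [1, 1]))


class TestSuccessiveStratify:
    def test_no_significant_marker_gives_score_only_tree(self):
        rng = np.random.default_rng(4)
        n = 120
        calls = make_calls(n, a=(rng.random(n) < 0.3).astype(int))
        samples = make_samples(n, rng.exponential(1, n), np.ones(n, int))
        score_ser = pd.Series(rng.random(n), index=samples.index)
        from survsig.signature import CoreScore

        score = CoreScore(pathway="s", core_genes=[], missing_genes=[],
                          scores=score_ser)
        tree = successive_stratify(calls, samples, score=score, alpha=1e-6)
        assert tree.nodes == []
        assert {n.condition for n in tree.terminal} == \
            {"score:low", "score:mid", "score:high"}

    def test_leaves_partition_cohort(self, nested_bundle):
        rel = collapse_trivially(nested_bundle)
        genes = nested_bundle.ground_truth["planted_sets"][0]["genes"]
        score = core_average_score(rel, genes, pathway="p")
        tree = successive_stratify(nested_bundle.arm_calls,
                                   nested_bundle.samples, score=score)
        members = [m for node in tree.leaves() for m in node.members]
        assert sorted(members) == sorted(nested_bundle.samples.index)

    def test_child_n_strictly_decreasing(self, nested_bundle):
        tree = successive_stratify(nested_bundle.arm_calls,
                                   nested_bundle.samples)
        total = len(nested_bundle.samples)
        remaining = total
        for node in tree.nodes:
            assert node.n < remaining
            remaining -= node.n

    def test_nested_markers_recovered_in_planted_order(self):
        strict = 0
        for seed in range(20):
            b = simulate_cohort(nested_arm_config(seed))
            rel = collapse_trivially(b)
            genes = b.ground_truth["planted_sets"][0]["genes"]
            score = core_average_score(rel, genes, pathway="p")
            labels = successive_stratify(
                b.arm_calls, b.samples, score=score).split_labels
            strict += (len(labels) >= 2
                       and labels[0] == "8q_loss:protective"
                       and labels[1] == "9p_gain:risk")
        assert strict >= 16

    def test_split_nodes_annotated(self, nested_bundle):
        rel = collapse_trivially(nested_bundle)
        genes = nested_bundle.ground_truth["planted_sets"][0]["genes"]
        score = core_average_score(rel, genes, pathway="p")
        tree = successive_stratify(nested_bundle.arm_calls,
                                   nested_bundle.samples, score=score)
        assert tree.nodes, "expected at least one split on the nested cohort"
        node = tree.nodes[0]
        assert node.logrank_vs_rest is not None
        assert np.isfinite(node.mean_score)
        assert 0 <= node.mannwhitney_p <= 1
        d = tree.to_dict()
        assert d["splits"][0]["n"] == node.n
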