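"""Manual shift-perturbation scoring and the PCA cross-validation."""

from dataclasses import replace

import numpy as np
import pytest

from siapca import (
    PeakEntry,
    PeakList,
    compare_methods,
    pca_preference_table,
    sia_preference_table,
    sia_scores,
    simulate_sia_experiment,
    subset_sensitivity,
    weighted_delta,
)
from siapca.errors import PairingError
from siapca.scoring import PreferenceTable


def entry(pid, h, n):
    return PeakEntry(pid, h, n, 1.0)


class TestWeightedDelta:
    def test_no_shift_is_zero(self):
        assert weighted_delta(entry("a", 8.0, 120.0), entry("a", 8.0, 120.0)) == 0.0

    def test_pure_proton_shift_ignores_alpha(self):
        for alpha in (0.1, 0.2, 0.5):
            assert weighted_delta(
                entry("a", 8.0, 120.0), entry("a", 8.03, 120.0), alpha
            ) == pytest.approx(0.03, abs=1e-12)

    def test_combined_shift(self):
        # sqrt(0.03^2 + (0.2 * 0.15)^2) = sqrt(2) * 0.03
        assert weighted_delta(
            entry("a", 8.0, 120.0), entry("a", 8.03, 120.15), alpha=0.2
        ) == pytest.approx(0.042426, abs=1e-6)

    def test_id_mismatch_is_pairing_error(self):
        with pytest.raises(PairingError):
            weighted_delta(entry("a", 8, 120), entry("b", 8, 120))


def lists_with_deltas(deltas_by_base):
    """One peak whose ¹H shift against each pool equals the given Δδ."""
    free = PeakList([entry("p1", 8.0, 120.0)])
    bound = {
        base: PeakList([entry("p1", 8.0 + d, 120.0)])
        for base, d in deltas_by_base.items()
    }
    return free, bound


class TestSiaScores:
    def test_normalization_by_largest_shift(self):
        free, bound = lists_with_deltas({"A": 0.05, "C": 0.10, "G": 0.40, "U": 0.20})
        scores, records = sia_scores(free, bound, ["p1"])
        assert scores == pytest.approx({"A": 0.125, "C": 0.25, "G": 1.0, "U": 0.5})
        assert records[0].normalized["G"] == 1.0

    def test_proportional_peaks_add_no_information(self):
        free = PeakList([entry("p1", 8.0, 120.0), entry("p2", 9.0, 110.0)])
        bound = {
            base: PeakList(
                [entry("p1", 8.0 + d, 120.0), entry("p2", 9.0 + 3 * d, 110.0)]
            )
            for base, d in {"A": 0.01, "C": 0.02, "G": 0.08, "U": 0.04}.items()
        }
        one, _ = sia_scores(free, bound, ["p1"])
        both, _ = sia_scores(free, bound, ["p1", "p2"])
        assert both == pytest.approx(one)

    def test_scale_invariance(self):
        free, bound = lists_with_deltas({"A": 0.05, "C": 0.10, "G": 0.40, "U": 0.20})
        scaled = {
            b: PeakList([entry("p1", 8.0 + 7 * (pl.entries[0].delta_h - 8.0), 120.0)])
            for b, pl in bound.items()
        }
        s1, _ = sia_scores(free, bound, ["p1"])
        s2, _ = sia_scores(free, scaled, ["p1"])
        assert s2 == pytest.approx(s1)

    def test_max_normalized_value_is_one_per_peak(self, noiseless_small_config):
        sim = simulate_sia_experiment(noiseless_small_config)
        responsive = list(sim.model.dmax_by_peak)[:8]
        _, records = sia_scores(sim.free_peaks, sim.bound_peaks[1], responsive)
        for rec in records:
            if not rec.excluded:
                assert max(rec.normalized.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_peak_excluded_and_reported(self):
        free = PeakList([entry("live", 8.0, 120.0), entry("dead", 9.0, 110.0)])
        bound = {
            b: PeakList([entry("live", 8.0 + d, 120.0), entry("dead", 9.0, 110.0)])
            for b, d in {"A": 0.01, "C": 0.02, "G": 0.08, "U": 0.04}.items()
        }
        scores, records = sia_scores(free, bound, ["live", "dead"])
        dead = [r for r in records if r.assignment_id == "dead"][0]
        assert dead.excluded
        assert scores["G"] == 1.0  # mean over the single informative peak

    def test_scores_proportional_to_f_bound_noiseless(self, noiseless_small_config):
        sim = simulate_sia_experiment(noiseless_small_config)
        responsive = list(sim.model.dmax_by_peak)[:10]
        scores, _ = sia_scores(sim.free_peaks, sim.bound_peaks[1], responsive)
        f = {b: sim.f_bound[(1, b)] for b in "ACGU"}
        fmax = max(f.values())
        for b in "ACGU":
            assert scores[b] == pytest.approx(f[b] / fmax, rel=1e-9)

    def test_missing_id_names_peak_and_base(self):
        free, bound = lists_with_deltas({"A": 0.1, "C": 0.1, "G": 0.1, "U": 0.1})
        bound["G"] = PeakList([entry("other", 8.0, 120.0)])
        with pytest.raises(PairingError, match="p1.*G"):
            sia_scores(free, bound, ["p1"])


class TestSubsetSensitivity:
    def test_identical_subsets_deviate_zero(self):
        free, bound = lists_with_deltas({"A": 0.05, "C": 0.1, "G": 0.4, "U": 0.2})
        dev = subset_sensitivity(free, bound, [["p1"], ["p1"]])
        assert all(v == 0.0 for v in dev.values())

    def test_proportional_shifts_make_selection_irrelevant(self):
        free = PeakList([entry(f"p{i}", 8.0 + 0.1 * i, 120.0) for i in range(4)])
        bound = {
            base: PeakList(
                [entry(f"p{i}", 8.0 + 0.1 * i + (1 + i) * d, 120.0) for i in range(4)]
            )
            for base, d in {"A": 0.01, "C": 0.02, "G": 0.08, "U": 0.04}.items()
        }
        dev = subset_sensitivity(free, bound, [["p0", "p1"], ["p2", "p3"]])
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in dev.values())

    def test_measurement_error_produces_selection_bias(self, noiseless_small_config):
        # exact fast-exchange lists carry no bias (normalisation removes the
        # per-peak scale); position read-out error re-introduces it
        sim = simulate_sia_experiment(noiseless_small_config)
        responsive = list(sim.model.dmax_by_peak)
        half = len(responsive) // 2
        exact = subset_sensitivity(
            sim.free_peaks, sim.bound_peaks[1], [responsive[:half], responsive[half:]]
        )
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in exact.values())

        rng = np.random.default_rng(3)
        measured = {
            b: PeakList(
                [
                    PeakEntry(e.assignment_id, e.delta_h + rng.normal(0, 0.003),
                              e.delta_n + rng.normal(0, 0.02), e.intensity)
                    for e in sim.bound_peaks[1][b]
                ]
            )
            for b in "ACGU"
        }
        noisy = subset_sensitivity(
            sim.free_peaks, measured, [responsive[:half], responsive[half:]]
        )
        assert max(noisy.values()) > 0.01


class TestCompareMethods:
    def manual_tables(self, order_a, order_b):
        def table(order, method):
            scores = {(1, b): 1.0 - 0.2 * order.index(b) for b in "ACGU"}
            return PreferenceTable(method=method, scores=scores)

        return table(order_a, "pca"), table(order_b, "sia_manual")

    def test_identical_rankings_tau_one(self):
        t1, t2 = self.manual_tables(list("GUCA"), list("GUCA"))
        t1.diagnostics = {1: {"component_distances": {1: {b: 0.1 for b in "ACGU"}}}}
        t2.diagnostics = {1: {"mean_delta": {b: 0.1 for b in "ACGU"}}}
        rep = compare_methods(t1, t2)
        assert rep.kendall_tau[1] == pytest.approx(1.0)
        assert rep.exact_match[1]

    def test_adjacent_transposition_tau_two_thirds(self):
        t1, t2 = self.manual_tables(list("GUCA"), list("GCUA"))
        t1.diagnostics = {1: {"component_distances": {1: {b: 0.1 for b in "ACGU"}}}}
        t2.diagnostics = {1: {"mean_delta": {b: 0.1 for b in "ACGU"}}}
        rep = compare_methods(t1, t2)
        assert rep.kendall_tau[1] == pytest.approx(2 / 3)
        assert not rep.exact_match[1]

    def test_position_mismatch_raises(self):
        t1, t2 = self.manual_tables(list("GUCA"), list("GUCA"))
        t2.scores = {(2, b): v for (_, b), v in t2.scores.items()}
        with pytest.raises(ValueError):
            compare_methods(t1, t2)

    def test_noiseless_simulation_full_agreement(self, noiseless_small_config):
        sim = simulate_sia_experiment(noiseless_small_config)
        pca_table, _ = pca_preference_table(sim.stacks)
        responsive = list(sim.model.dmax_by_peak)[:10]
        sia_table = sia_preference_table(
            {p: sim.free_peaks for p in sim.stacks}, sim.bound_peaks, responsive
        )
        rep = compare_methods(pca_table, sia_table)
        for pos in sim.stacks:
            assert rep.kendall_tau[pos] == pytest.approx(1.0)
            assert sia_table.ranking(pos) == sim.true_ranking(pos)

    def test_component_two_correlates_best_with_shifts(self, small_config):
        cfg = replace(small_config, seed=11)
        sim = simulate_sia_experiment(cfg)
        pca_table, _ = pca_preference_table(sim.stacks)
        responsive = list(sim.model.dmax_by_peak)[:10]
        sia_table = sia_preference_table(
            {p: sim.free_peaks for p in sim.stacks}, sim.bound_peaks, responsive
        )
        rep = compare_methods(pca_table, sia_table)
        assert rep.best_component() == 2
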