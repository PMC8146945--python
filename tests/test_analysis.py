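import math

import numpy as np
import pytest

import snnmorph as sm
from snnmorph.analysis import (
    UNASSIGNED,
    ZONE_ORDER,
    ConnectivityDelta,
    RegionScheme,
    mean_delta,
    relative_change,
)
from snnmorph.plasticity import STDPParams, TrainedModel
from snnmorph.reservoir import LIFParams, NeuronGrid, SWCParams, SpikeActivity

from test_reservoir import line_grid


def toy_trained(weights, conn=None, grid=None, condition="Pre"):
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    conn = (weights != 0) if conn is None else conn
    grid = grid or line_grid(n)
    model = sm.ReservoirModel(
        grid=grid, weights=weights, connections=conn,
        lif=LIFParams(), swc=SWCParams(), seed=0,
    )
    return TrainedModel(
        model=model, trained_on=condition,
        activity=SpikeActivity(np.array([], int), np.array([], int), 0),
        params=STDPParams(), initial_weights=weights.copy(),
    )


def delta_from_arrays(w_pre, w_post, grid=None):
    w_pre = np.asarray(w_pre, float)
    w_post = np.asarray(w_post, float)
    m = len(w_pre)
    grid = grid or line_grid(m + 1)
    return ConnectivityDelta(
        sources=np.zeros(m, np.int64),
        targets=np.arange(1, m + 1, dtype=np.int64) % grid.n_neurons,
        w_pre=w_pre, w_post=w_post, grid=grid, labels=("Pre", "Post"),
    )


class TestSubtractModels:
    def test_self_subtraction_is_zero(self):
        w = np.array([[0, 0.2, 0.5], [0, 0, 0.1], [0, 0, 0]])
        m = toy_trained(w)
        delta = sm.subtract_models(m, m)
        assert np.all(delta.delta == 0)

    def test_antisymmetry(self):
        conn = np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]], bool)
        a = toy_trained(np.array([[0, 0.2, 0.5], [0, 0, 0.1], [0, 0, 0]]), conn)
        b = toy_trained(np.array([[0, 0.4, 0.1], [0, 0, 0.3], [0, 0, 0]]), conn)
        ab = sm.subtract_models(a, b)
        ba = sm.subtract_models(b, a)
        assert np.array_equal(ab.delta, -ba.delta)

    def test_toy_arithmetic(self):
        conn = np.zeros((3, 3), bool)
        conn[0, 1] = conn[1, 2] = True
        pre = toy_trained(np.array([[0, 0.2, 0], [0, 0, 0.5], [0, 0, 0]]), conn)
        post = toy_trained(np.array([[0, 0.4, 0], [0, 0, 0.1], [0, 0, 0]]), conn, condition="Post")
        delta = sm.subtract_models(pre, post)
        assert delta.delta.tolist() == [pytest.approx(0.2), pytest.approx(-0.4)]
        assert delta.labels == ("Pre", "Post")

    def test_mismatched_grids_error(self):
        a = toy_trained(np.array([[0, 0.1], [0, 0]]), grid=line_grid(2))
        b = toy_trained(np.array([[0, 0.1], [0, 0]]), grid=line_grid(2, spacing=11.0))
        with pytest.raises(ValueError, match="grid"):
            sm.subtract_models(a, b)

    def test_mismatched_sparsity_error(self):
        conn_a = np.array([[0, 1], [0, 0]], bool)
        conn_b = np.array([[0, 1], [1, 0]], bool)
        a = toy_trained(np.array([[0, 0.1], [0, 0]]), conn_a)
        b = toy_trained(np.array([[0, 0.1], [0.2, 0]]), conn_b)
        with pytest.raises(ValueError, match="sparsity"):
            sm.subtract_models(a, b)


class TestRetainTop:
    @pytest.mark.parametrize("m,expected", [(1, 1), (19, 1), (20, 1), (200, 10), (10**5, 5000)])
    def test_retention_cardinality(self, m, expected):
        rng = np.random.default_rng(m)
        delta = delta_from_arrays(rng.uniform(0.1, 1, m), rng.uniform(1.1, 2, m))
        out = sm.retain_top(delta, 0.05)
        assert int(out.retained.sum()) == expected == math.ceil(0.05 * m)

    def test_fraction_one_keeps_all_nonzero(self):
        delta = delta_from_arrays([0.1, 0.2, 0.3], [0.1, 0.5, 0.9])  # first edge unchanged
        out = sm.retain_top(delta, 1.0)
        assert int(out.retained.sum()) == 2
        assert not out.retained[0]

    def test_nesting(self):
        rng = np.random.default_rng(0)
        delta = delta_from_arrays(rng.uniform(0.1, 1, 100), rng.uniform(0, 2, 100))
        small = set(sm.retain_top(delta, 0.05).retained_indices())
        large = set(sm.retain_top(delta, 0.10).retained_indices())
        assert small <= large

    def test_relative_ranking_prefers_small_base(self):
        # same |delta|, smaller w_pre -> larger relative change
        delta = delta_from_arrays([0.5, 0.05], [0.6, 0.15])
        out = sm.retain_top(delta, 0.5)
        assert out.retained_indices().tolist() == [1]

    def test_absolute_ranking_flag(self):
        delta = delta_from_arrays([0.5, 0.05], [1.0, 0.25])
        out = sm.retain_top(delta, 0.5, relative=False)
        assert out.retained_indices().tolist() == [0]

    def test_tie_break_by_edge_index(self):
        delta = delta_from_arrays([0.1, 0.1, 0.1], [0.2, 0.2, 0.2])
        out = sm.retain_top(delta, 0.4)  # ceil(1.2) = 2 of 3 equal scores
        assert out.retained_indices().tolist() == [0, 1]

    def test_fraction_validation(self):
        delta = delta_from_arrays([0.1], [0.2])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                sm.retain_top(delta, bad)

    def test_retained_subset_of_nonzero(self):
        delta = delta_from_arrays([0.1, 0.2, 0.3], [0.1, 0.2, 0.9])
        out = sm.retain_top(delta, 1.0)
        assert set(out.retained_indices()) <= set(np.nonzero(delta.delta)[0])


class TestRegionScheme:
    def test_ten_zones(self):
        scheme = sm.default_region_scheme()
        assert len(scheme.zones) == 10
        assert set(scheme.zones) == set(ZONE_ORDER)

    def test_zone_lists_disjoint(self):
        scheme = sm.default_region_scheme()
        all_labels = [lab for labs in scheme.zones.values() for lab in labs]
        assert len(all_labels) == len(set(all_labels))

    def test_exact_membership_examples(self):
        assert sm.electrode_zone("P3") == "centroparietal_l"
        assert sm.electrode_zone("Fp2") == "frontal_r"
        assert sm.electrode_zone("TP8") == "temporal_r"
        assert sm.electrode_zone("PO5") == "occipitoparietal_l"
        assert sm.electrode_zone("C6") == "frontocentral_r"

    def test_aux_and_midline_unassigned(self, montage):
        for lab in ("AUX1", "AUX2", "Cz", "Fpz", "Iz"):
            assert sm.electrode_zone(lab, montage=montage) == UNASSIGNED

    def test_unknown_label_raises(self, montage):
        with pytest.raises(KeyError):
            sm.electrode_zone("XX1", montage=montage)

    def test_duplicate_electrode_rejected(self):
        with pytest.raises(ValueError, match="two zones"):
            RegionScheme({"a": ("P3",), "b": ("P3",)})

    def test_hemisphere_naming(self):
        scheme = sm.default_region_scheme()
        for zone in scheme.zones:
            side = scheme.hemisphere(zone)
            assert side == ("left" if zone.endswith("_l") else "right")


class TestSummarizeRegions:
    def make_neuron_delta(self, montage, grid, edges):
        """Build a delta whose neurons sit exactly at given electrodes."""
        imap = sm.map_inputs(montage, grid)
        src, tgt, wpre, wpost = [], [], [], []
        for (e_from, e_to, d) in edges:
            src.append(imap[e_from])
            tgt.append(imap[e_to])
            wpre.append(0.3)
            wpost.append(0.3 + d)
        delta = ConnectivityDelta(
            sources=np.array(src, np.int64), targets=np.array(tgt, np.int64),
            w_pre=np.array(wpre), w_post=np.array(wpost),
            grid=grid, labels=("Pre", "Post"),
        )
        return sm.retain_top(delta, 1.0), imap

    def test_all_left_edges_give_dominance_minus_one(self, montage, analysis_grid):
        delta, imap = self.make_neuron_delta(
            montage, analysis_grid,
            [("P3", "P5", 0.2), ("FC3", "FC5", -0.1)],
        )
        summary = sm.summarize_regions(delta, input_map=imap, montage=montage)
        assert summary.dominance == -1.0

    def test_all_right_edges_give_dominance_plus_one(self, montage, analysis_grid):
        delta, imap = self.make_neuron_delta(
            montage, analysis_grid, [("P4", "P6", 0.2)]
        )
        summary = sm.summarize_regions(delta, input_map=imap, montage=montage)
        assert summary.dominance == 1.0

    def test_empty_retained_all_zero(self, montage, analysis_grid):
        delta, imap = self.make_neuron_delta(
            montage, analysis_grid, [("P3", "P5", 0.0)]
        )
        summary = sm.summarize_regions(delta, input_map=imap, montage=montage)
        assert summary.dominance == 0.0
        assert not summary.increase.any()
        assert not summary.decrease.any()

    def test_increase_decrease_split(self, montage, analysis_grid):
        delta, imap = self.make_neuron_delta(
            montage, analysis_grid,
            [("P3", "P5", 0.2), ("P3", "P1", -0.3)],
        )
        summary = sm.summarize_regions(delta, input_map=imap, montage=montage)
        zi = ZONE_ORDER.index("centroparietal_l")
        assert summary.increase[zi, zi] == pytest.approx(0.2)
        assert summary.decrease[zi, zi] == pytest.approx(-0.3)
        assert np.all(summary.increase >= 0)
        assert np.all(summary.decrease <= 0)

    def test_cross_zone_edge_lands_in_off_diagonal(self, montage, analysis_grid):
        delta, imap = self.make_neuron_delta(
            montage, analysis_grid, [("P3", "O1", 0.4)]
        )
        summary = sm.summarize_regions(delta, input_map=imap, montage=montage)
        zi = ZONE_ORDER.index("centroparietal_l")
        zj = ZONE_ORDER.index("occipitoparietal_l")
        assert summary.increase[zi, zj] == pytest.approx(0.4)


class TestRecoveryScore:
    def _summary_with(self, montage, analysis_grid, edges):
        helper = TestSummarizeRegions()
        delta, imap = helper.make_neuron_delta(montage, analysis_grid, edges)
        return sm.summarize_regions(delta, input_map=imap, montage=montage)

    def test_perfect_recovery(self, montage, analysis_grid):
        summary = self._summary_with(
            montage, analysis_grid, [("P3", "P5", 0.5), ("FC3", "FC5", 0.4)]
        )
        planted = (
            sm.CouplingEdge("P5", "P3", 4, 0.9),
            sm.CouplingEdge("FC5", "FC3", 3, 0.9),
        )
        assert sm.recovery_score(summary, planted) == 1.0

    def test_missed_zone_scores_half(self, montage, analysis_grid):
        summary = self._summary_with(montage, analysis_grid, [("P3", "P5", 0.5)])
        planted = (
            sm.CouplingEdge("P5", "P3", 4, 0.9),
            sm.CouplingEdge("F6", "F4", 3, 0.9),  # nothing recovered there
        )
        assert sm.recovery_score(summary, planted) == 0.5

    def test_empty_planted_errors(self, montage, analysis_grid):
        summary = self._summary_with(montage, analysis_grid, [("P3", "P5", 0.5)])
        with pytest.raises(ValueError, match="planted"):
            sm.recovery_score(summary, ())


class TestMeanDelta:
    def test_mean_of_deltas(self):
        a = delta_from_arrays([0.1, 0.2], [0.3, 0.2])
        b = delta_from_arrays([0.3, 0.4], [0.1, 0.8])
        avg = mean_delta([a, b])
        assert avg.delta == pytest.approx([(0.2 - 0.2) / 1, (0.0 + 0.4) / 2])

    def test_mismatched_patterns_rejected(self):
        a = delta_from_arrays([0.1], [0.3])
        b = delta_from_arrays([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValueError):
            mean_delta([a, b])


def test_relative_change_floor():
    delta = delta_from_arrays([0.0, 1.0], [0.5, 1.5])
    rel = relative_change(delta)
    assert rel[0] == pytest.approx(0.5 / 1e-6)
    assert rel[1] == pytest.approx(0.5)
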