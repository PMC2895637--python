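"""Weight summaries, fidelity classifiers, expansion curve, recall speed."""

import math

import numpy as np
import pandas as pd
import pytest

from ca3net import analysis as A
from ca3net.drive import PlaceMap, RouteConfig


def make_map(n_fields, cells_per_field):
    return PlaceMap(np.repeat(np.arange(n_fields), cells_per_field))


def raster(pairs):
    return pd.DataFrame(pairs, columns=["time_ms", "neuron_id"])


class TestWeightSummary:
    def test_uniform_matrix_no_separation(self):
        pm = make_map(10, 1)
        w = np.full((10, 10), 0.3)
        ws = A.weight_summary(w, pm, "hetero")
        assert ws.foreground_mean == pytest.approx(ws.background_mean)
        assert ws.p_value == pytest.approx(1.0)

    def test_idealized_matrix_separates(self):
        pm = make_map(20, 1)
        mask = A.foreground_mask(pm, "hetero")
        w = np.where(mask, 1.0, 0.0)
        ws = A.weight_summary(w, pm, "hetero")
        assert ws.foreground_mean == 1.0 and ws.background_mean == 0.0
        assert ws.p_value < 1e-6

    def test_foreground_definitions(self):
        pm = make_map(10, 2)
        hetero = A.foreground_mask(pm, "hetero")
        auto = A.foreground_mask(pm, "auto")
        dual = A.foreground_mask(pm, "dual")
        f = pm.field_of
        ahead = (f[None, :] - f[:, None]) % 10
        assert not hetero[ahead == 0].any()       # same-field excluded
        assert auto[0, 1] and not auto[0, 2]      # same-field only
        assert np.array_equal(dual, hetero | auto)
        assert not dual.diagonal().any()

    def test_relabeling_invariance(self):
        """Classification statistics ignore neuron order within a field."""
        pm = make_map(5, 2)
        rng = np.random.default_rng(0)
        w = rng.random((10, 10))
        base = A.weight_summary(w, pm, "dual")
        # swap the two cells of field 0 (indices 0, 1)
        perm = np.arange(10)
        perm[[0, 1]] = [1, 0]
        ws = A.weight_summary(w[np.ix_(perm, perm)], pm, "dual")
        assert ws.p_value == pytest.approx(base.p_value)
        assert ws.foreground_mean == pytest.approx(base.foreground_mean)


class TestSequenceClassifier:
    def test_strictly_ordered_raster_all_before(self):
        pm = make_map(10, 1)
        r = raster([(k, k) for k in range(10)])
        rep = A.classify_sequence_recall(r, pm, wrap=False)
        assert rep.before == 10 and rep.after == 0 and rep.same_time == 0
        assert rep.fraction_non_erroneous == 1.0

    def test_circular_wrap_marks_last_cell(self):
        """On the circular route the last field's successor is field 0,
        which already fired, so the final cell of a sweep is erroneous."""
        pm = make_map(10, 1)
        r = raster([(k, k) for k in range(10)])
        rep = A.classify_sequence_recall(r, pm)
        assert rep.before == 9 and rep.after == 1

    def test_silent_cell_is_erroneous(self):
        pm = make_map(10, 1)
        r = raster([(k, k) for k in range(9)])  # cell 9 silent
        rep = A.classify_sequence_recall(r, pm)
        assert rep.after == 1

    def test_tie_counts_as_same_time(self):
        pm = make_map(3, 1)
        r = raster([(5, 0), (5, 1), (7, 2)])
        rep = A.classify_sequence_recall(r, pm)
        assert rep.same_time >= 1

    def test_empty_raster_all_erroneous(self):
        pm = make_map(4, 1)
        rep = A.classify_sequence_recall(raster([]), pm)
        assert rep.after == 4 and rep.before == 0

    def test_fractions_sum_to_one(self):
        pm = make_map(6, 1)
        r = raster([(1, 0), (1, 1), (9, 3), (2, 5)])
        rep = A.classify_sequence_recall(r, pm)
        total = rep.fraction_before + rep.fraction_same + rep.fraction_after
        assert total == pytest.approx(1.0)


class TestPatternCompletion:
    def test_full_completion_no_errors(self):
        r = raster([(0, 0), (0, 1), (6, 2), (6, 3), (6, 4)])
        rep = A.classify_pattern_completion(r, cued={0, 1},
                                            pattern={0, 1, 2, 3, 4})
        assert rep.accurate_fraction == 1.0
        assert rep.erroneous_count == 0

    def test_in_window_bounds(self):
        r = raster([(0, 0), (5, 1), (10, 2), (25, 3)])
        rep = A.classify_pattern_completion(r, cued={0},
                                            pattern={0, 1, 2, 3})
        assert rep.accurate_fraction == pytest.approx(2.0 / 3.0)  # 25 ms late

    def test_off_pattern_spike_is_erroneous(self):
        r = raster([(0, 0), (12, 9)])
        rep = A.classify_pattern_completion(r, cued={0}, pattern={0, 1})
        assert rep.erroneous_count == 1

    def test_cue_outside_pattern_rejected(self):
        with pytest.raises(ValueError):
            A.classify_pattern_completion(raster([]), cued={5}, pattern={0, 1})


class TestExpansionCurve:
    def test_fixed_phase_raster_recovered(self):
        """A synthetic raster with spikes at a known theta phase yields that
        phase exactly."""
        route = RouteConfig(n_fields=1, offset_cm=160.0, n_laps=2)
        pm = make_map(1, 1)
        # entry segment spans the first second of each 16-s lap; theta period
        # is 125 ms, so t = lap_start + 31 ms sits at phase 2*pi*31/125
        spikes = [(31, 0), (16_031, 0)]
        curve = A.expansion_curve(raster(spikes), route, pm)
        expected = (2 * math.pi * 31 / 125.0) % (2 * math.pi)
        assert curve.entry_phase[0] == pytest.approx(expected)
        assert curve.entry_phase[1] == pytest.approx(expected)
        assert np.isnan(curve.exit_phase[0])

    def test_empty_lap_is_missing(self):
        route = RouteConfig(n_fields=1, offset_cm=160.0, n_laps=3)
        pm = make_map(1, 1)
        curve = A.expansion_curve(raster([(31, 0)]), route, pm)
        assert not np.isnan(curve.entry_phase[0])
        assert np.isnan(curve.entry_phase[1]) and np.isnan(curve.entry_phase[2])


class TestEffectiveSpeed:
    def _route(self):
        # 2-m circular route (20 fields offset by 10 cm)
        return RouteConfig(n_fields=20, offset_cm=10.0, cells_per_field=1)

    def test_return_after_25ms_is_80_m_s(self):
        route, pm = self._route(), make_map(20, 1)
        spikes = [(0, 0)] + [(k, k) for k in range(1, 20)] + [(25, 0)]
        v = A.effective_speed(raster(spikes), route, pm, cue_field=0)
        assert v == pytest.approx(80.0)

    def test_return_after_80ms_is_25_m_s(self):
        route, pm = self._route(), make_map(20, 1)
        spikes = [(0, 0)] + [(k, k) for k in range(1, 20)] + [(80, 0)]
        v = A.effective_speed(raster(spikes), route, pm, cue_field=0)
        assert v == pytest.approx(25.0)

    def test_failed_propagation_returns_none(self):
        route, pm = self._route(), make_map(20, 1)
        spikes = [(0, 0), (3, 1), (6, 2)]  # dies after field 2
        assert A.effective_speed(raster(spikes), route, pm, 0) is None

    def test_early_reentry_not_counted(self):
        """A cued-field spike before the loop completes is not the return."""
        route, pm = self._route(), make_map(20, 1)
        spikes = ([(0, 0), (5, 0)] + [(k, k) for k in range(1, 20)]
                  + [(40, 0)])
        v = A.effective_speed(raster(spikes), route, pm, cue_field=0)
        assert v == pytest.approx(2.0 / 0.040)
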