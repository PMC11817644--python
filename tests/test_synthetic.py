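"""Synthetic generators: field structure, TLD noise model, event logs."""

import numpy as np
import pytest

from cathdose import synthetic
from cathdose.binning import filter_events
from cathdose.geometry import region_mask
from cathdose.synthetic import EventLogParams, ScatterFieldParams
from cathdose.tld import reading_to_dose


def region_mean_of_field(field, grid, thresholds, region):
    """Brute-force mask-average of the ground-truth field."""
    total, count = 0.0, 0
    for geom in grid.slices:
        yy, xx = np.nonzero(region_mask(geom, region, thresholds))
        vals = field.at_array(geom.slice_no, xx, yy)
        total += vals.sum()
        count += len(vals)
    return total / count


class TestScatterField:
    def test_infinite_attenuation_gives_constant_field(self, small_grid):
        params = ScatterFieldParams(reference_cc=0.8, attenuation_length=1e12)
        field = synthetic.make_scatter_field(params, small_grid)
        vals = [field(2, (40, 40)), field(5, (80, 90)), field(3, (64, 64))]
        assert np.allclose(vals, 0.8, rtol=1e-9)

    def test_one_attenuation_length_along_gradient_gives_ratio_e(self, small_grid):
        ps = small_grid.pixel_spacing
        L = 40 * ps  # one attenuation length spans 40 pixels in-plane
        params = ScatterFieldParams(
            reference_cc=1.0, gradient_direction=(1, 0, 0), attenuation_length=L
        )
        field = synthetic.make_scatter_field(params, small_grid)
        ratio = field(3, (30, 64)) / field(3, (70, 64))
        assert ratio == pytest.approx(np.e, rel=1e-9)

    def test_field_positive_and_nonincreasing_along_gradient(self, small_field, small_grid):
        g = np.asarray(small_field.params.gradient_direction[:2])
        start = np.array([64.0, 64.0])
        prev = np.inf
        for t in np.linspace(0, 30, 7):
            p = start + t * g / small_grid.pixel_spacing
            v = small_field(3, tuple(p))
            assert 0 < v <= prev + 1e-12
            prev = v

    def test_default_field_is_left_lower_front_skewed(
        self, small_field, small_grid, small_thresholds
    ):
        m = lambda r: region_mean_of_field(small_field, small_grid, small_thresholds, r)
        assert m("left") > m("right")
        assert m("lower") > m("upper")
        assert m("front") > m("rear")


class TestSimulatedReadings:
    def _session(self):
        return synthetic.default_sessions()[1]  # LAO30, P_KA 500

    def test_noise_free_readings_invert_exactly(self, small_field, small_grid):
        session = self._session()
        readings = synthetic.simulate_tld_readings(
            small_field, small_grid, session, noise_cv=0.0, seed=7
        )
        index = small_grid.position_index()
        assert len(readings) == 2 * len(index)
        for r in readings:
            slice_no, xy = index[r.position_id]
            truth = (
                small_field.at_eye(r.position_id)
                if slice_no is None
                else small_field.at(slice_no, xy)
            ) * session.total_pka
            dose, _ = reading_to_dose(r)
            assert dose == pytest.approx(truth, rel=1e-12)

    def test_same_seed_reproduces_readings(self, small_field, small_grid):
        session = self._session()
        a = synthetic.simulate_tld_readings(small_field, small_grid, session, 0.02, seed=3)
        b = synthetic.simulate_tld_readings(small_field, small_grid, session, 0.02, seed=3)
        assert a == b

    def test_noise_cv_is_calibrated(self, small_field, small_grid):
        """With noise_cv = 0.02 the recovered-dose noise factors have a
        sample CV in [0.01, 0.03] over >= 100 replicates."""
        session = self._session()
        index = small_grid.position_index()
        ratios = []
        for seed in range(2):
            for r in synthetic.simulate_tld_readings(
                small_field, small_grid, session, noise_cv=0.02, seed=seed
            ):
                slice_no, xy = index[r.position_id]
                truth = (
                    small_field.at_eye(r.position_id)
                    if slice_no is None
                    else small_field.at(slice_no, xy)
                ) * session.total_pka
                dose, _ = reading_to_dose(r)
                ratios.append(dose / truth)
        assert len(ratios) >= 100
        cv = np.std(ratios) / np.mean(ratios)
        assert 0.01 <= cv <= 0.03


class TestEventLog:
    def test_all_mass_on_one_bin(self):
        params = EventLogParams(
            n_events=500, angle_weights={(30, -30): 1.0}, seed=1
        )
        events = synthetic.simulate_event_log(params)
        assert ((events.rotation_deg > 15) & (events.rotation_deg <= 45)).all()
        assert ((events.angulation_deg >= -45) & (events.angulation_deg < -15)).all()

    def test_fluoro_pka_share_matches_target(self):
        params = EventLogParams(n_events=20_000, fluoro_pka_fraction=0.641, seed=2)
        events = synthetic.simulate_event_log(params)
        share = (
            events.loc[events.modality == "fluoroscopy", "pka_gycm2"].sum()
            / events.pka_gycm2.sum()
        )
        assert share == pytest.approx(0.641, abs=0.02)

    def test_out_of_range_mass_controls_retention(self):
        weights = dict(synthetic.DEFAULT_ANGLE_WEIGHTS)
        in_range = {k: v for k, v in weights.items() if k != "out_of_range"}
        total_in = sum(in_range.values())
        weights = {k: v / total_in * 0.9 for k, v in in_range.items()}
        weights["out_of_range"] = 0.1
        events = synthetic.simulate_event_log(
            EventLogParams(n_events=20_000, angle_weights=weights, seed=3)
        )
        result = filter_events(events)
        assert result.retained_fraction == pytest.approx(0.90, abs=0.02)

    def test_schema_and_positivity(self):
        events = synthetic.simulate_event_log(EventLogParams(n_events=200, seed=4))
        assert list(events.columns) == [
            "procedure_id",
            "modality",
            "rotation_deg",
            "angulation_deg",
            "pka_gycm2",
        ]
        assert (events.pka_gycm2 > 0).all()
        assert set(events.modality) <= {"fluoroscopy", "acquisition"}

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EventLogParams(angle_weights={(0, 0): 0.5})
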