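"""Tests for the factorial design and the calibrated ground-truth surfaces."""

import numpy as np
import pytest

import grnnfoa as g
from grnnfoa.synthetic import TOTAL_YIELD_CALIBRATION, Bump, TrueSurface


class TestDesign:
    def test_harvest_schedule_follows_two_day_intervals(self):
        design = g.default_design()
        assert design.harvest_days[13.0] == [15.0, 17.0, 19.0, 21.0, 23.0]
        assert design.harvest_days[17.0] == [19.0, 21.0, 23.0]

    def test_dose_and_ratio_levels(self):
        design = g.default_design()
        assert design.dose_levels == [2.5, 5.0, 10.0]
        assert len(design.elicitor_ratios) == 5

    def test_elicitor_arm_row_count(self):
        # 5 ratios x 3 doses x (5 + 3) harvests x 3 replicates
        assert len(g.default_design().rows()) == 360

    def test_control_arms_enter_as_zero_elicitor_rows(self):
        rows = g.default_design(include_controls=True).rows()
        controls = rows[(rows.ce_pct == 0) & (rows.cf_pct == 0)]
        assert len(rows) > 360 and len(controls) >= 48

    def test_invalid_harvest_before_adding_rejected(self):
        design = g.default_design()
        design.harvest_days[17.0] = [16.0]
        with pytest.raises(ValueError, match="strictly after"):
            design.rows()

    def test_nonpositive_dose_rejected(self):
        design = g.default_design()
        design.dose_levels = [0.0, 5.0]
        with pytest.raises(ValueError, match="dose"):
            design.validate()


class TestSimulate:
    def test_identity_chain_exact_at_zero_noise(self):
        surface = g.default_surface(noise_cv=0.0)
        ds = g.simulate(g.default_design(), surface, seed=1)
        assert (ds.total_ug_l == ds.intra_ug_l + ds.extra_ug_l).all()
        assert (ds.intra_ug_l == ds.intra_ug_g * ds.dw_g_l).all()
        np.testing.assert_allclose(
            ds.portion_pct, 100 * ds.extra_ug_l / ds.total_ug_l, rtol=1e-12
        )
        assert (ds[ds.columns[4:]] >= 0).all().all()

    def test_identities_hold_under_noise_too(self, default_dataset):
        ds = default_dataset
        assert (ds.total_ug_l == ds.intra_ug_l + ds.extra_ug_l).all()
        assert (ds.intra_ug_l == ds.intra_ug_g * ds.dw_g_l).all()

    def test_same_seed_is_byte_identical(self):
        design, surface = g.default_design(), g.default_surface()
        a = g.simulate(design, surface, seed=11).to_csv(index=False)
        b = g.simulate(design, surface, seed=11).to_csv(index=False)
        assert a == b

    def test_distinct_seeds_differ(self):
        design, surface = g.default_design(), g.default_surface()
        a = g.simulate(design, surface, seed=1)
        b = g.simulate(design, surface, seed=2)
        assert not np.allclose(a.dw_g_l, b.dw_g_l)

    def test_replicate_noise_cv_converges(self):
        design = g.DesignSpec(
            elicitor_ratios=[(50, 50)],
            dose_levels=[10.0],
            adding_days=[13.0],
            harvest_days={13.0: [21.0]},
            replicates=1000,
        )
        surface = g.default_surface(noise_cv=0.1)
        ds = g.simulate(design, surface, seed=4)
        cv = ds.dw_g_l.std() / ds.dw_g_l.mean()
        assert 0.08 <= cv <= 0.12

    def test_negative_noise_cv_rejected(self):
        surface = g.default_surface(noise_cv=0.1)
        surface.noise_cv = -0.1
        with pytest.raises(ValueError):
            g.simulate(g.default_design(), surface, seed=0)


class TestSurface:
    def test_total_yield_calibrated_to_reported_optimum(self):
        surface = g.default_surface(noise_cv=0.0)
        _x, peak = g.true_argmax(surface, "total_ug_l", resolution=41)
        assert peak == pytest.approx(TOTAL_YIELD_CALIBRATION, rel=0.01)

    def test_true_argmax_finds_configured_peak(self):
        surface = TrueSurface(
            dw=Bump((4.3, 5.4, 17.0, 20.7), (3, 3, 3, 3), 9.0, base=3.0),
            intra_l=Bump((4.3, 5.4, 17.0, 20.7), (3, 3, 3, 3), 200.0, base=1.0),
            extra=Bump((4.3, 5.4, 17.0, 20.7), (3, 3, 3, 3), 150.0, base=1.0),
            noise_cv=0.0,
        )
        x, _v = g.true_argmax(surface, "extra_ug_l", resolution=41)
        steps = np.array([10 / 40, 10 / 40, 4 / 40, 10 / 40])
        assert np.all(np.abs(x - np.array([4.3, 5.4, 17.0, 20.7])) <= steps + 1e-9)

    def test_true_argmax_on_constant_surface_returns_constant(self):
        surface = TrueSurface(
            dw=Bump((5, 5, 15, 20), (3, 3, 3, 3), 0.0, base=8.0),
            intra_l=Bump((5, 5, 15, 20), (3, 3, 3, 3), 0.0, base=40.0),
            extra=Bump((5, 5, 15, 20), (3, 3, 3, 3), 0.0, base=10.0),
            noise_cv=0.0,
        )
        _x, v = g.true_argmax(surface, "extra_ug_l")
        assert v == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_randomized_peak_recovered_within_grid_resolution(self, seed):
        rng = np.random.default_rng(seed)
        center = (
            rng.uniform(1, 9),
            rng.uniform(1, 9),
            rng.uniform(13.5, 16.5),
            rng.uniform(17, 22),
        )
        surface = TrueSurface(
            dw=Bump(center, (3, 3, 2, 3), 9.0, base=3.0),
            intra_l=Bump(center, (3, 3, 2, 3), 200.0, base=1.0),
            extra=Bump(center, (3, 3, 2, 3), 150.0, base=1.0),
            noise_cv=0.0,
        )
        x, _v = g.true_argmax(surface, "intra_ug_l", resolution=41)
        steps = np.array([10 / 40, 10 / 40, 4 / 40, 10 / 40])
        assert np.all(np.abs(x - np.asarray(center)) <= steps + 1e-9)

    def test_surface_json_round_trip(self):
        surface = g.default_surface()
        clone = TrueSurface.from_dict(surface.to_dict())
        X = g.default_design().rows().to_numpy()[:10]
        for a, b in zip(surface.primitives(X), clone.primitives(X)):
            np.testing.assert_array_equal(a, b)
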