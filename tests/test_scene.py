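"""Simulator: diffusion kernel, agent behaviors, rendering."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import microswarm as ms
from microswarm.scene import TRUTH_COLUMNS

from oracles import point_source_concentration


def small_config(**kw):
    defaults = dict(field_width=260.0, field_height=260.0, pixel_size=1.3,
                    n_frames=5, source_position=(130.0, 130.0),
                    source_amount=1.0, diffusion_coefficient=10.0,
                    pre_diffusion_time=30.0, rng_seed=0)
    defaults.update(kw)
    return ms.ChamberConfig(**defaults)


class TestDiffusion:
    def test_kernel_matches_direct_evaluation(self):
        """Concentration 100 µm from the source equals the closed form."""
        cfg = ms.ChamberConfig(source_position=(500.0, 400.0),
                               source_amount=1.0,
                               diffusion_coefficient=1000.0,
                               pre_diffusion_time=300.0)
        field = ms.diffuse_concentration(cfg, 0.0)
        expected = point_source_concentration(100.0, 300.0, 1000.0, 1.0)
        got = field.value_at(600.0, 400.0)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_maximum_at_source(self):
        cfg = small_config()
        field = ms.diffuse_concentration(cfg, 1.0)
        iy, ix = np.unravel_index(np.argmax(field.values),
                                  field.values.shape)
        x = (ix + 0.5) * cfg.pixel_size
        y = (iy + 0.5) * cfg.pixel_size
        assert abs(x - 130.0) <= cfg.pixel_size
        assert abs(y - 130.0) <= cfg.pixel_size
        assert (field.values >= 0).all()

    def test_mass_conservation_interior_source(self):
        """Grid-integrated mass matches the injected amount within 1%
        when the diffusion length is well inside the field."""
        cfg = small_config()
        field = ms.diffuse_concentration(cfg, 0.0)
        mass = field.values.sum() * cfg.pixel_size ** 2
        assert mass == pytest.approx(1.0, rel=0.01)

    def test_monotone_decay_along_rays(self):
        cfg = small_config()
        field = ms.diffuse_concentration(cfg, 0.0)
        for angle in (0.0, 0.7, 2.1, 4.0):
            rs = np.linspace(0, 120, 40)
            vals = [field.value_at(130 + r * math.cos(angle),
                                   130 + r * math.sin(angle)) for r in rs]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_singular_time_rejected(self):
        cfg = small_config(pre_diffusion_time=0.0)
        with pytest.raises(ValueError):
            ms.diffuse_concentration(cfg, 0.0)
        with pytest.raises(ValueError):
            ms.diffuse_concentration(small_config(), -1.0)


def make_field(cfg, amount=0.0):
    return ms.diffuse_concentration(
        ms.ChamberConfig(**{**cfg.__dict__, "source_amount": amount}), 0.0)


class TestStepAgents:
    def test_zero_speed_no_flow_stationary(self):
        cfg = small_config()
        field = make_field(cfg)
        a = ms.AgentState(0, "bacterium", "swimming", 100.0, 100.0,
                          0.3, 0.0, 2.0)
        rng = np.random.default_rng(0)
        out = ms.step_agents([a], field, None, 0.0735, rng, config=cfg)
        assert out[0].x == 100.0 and out[0].y == 100.0

    def test_sessile_and_encysted_never_move(self):
        cfg = small_config()
        field = make_field(cfg)
        rng = np.random.default_rng(0)
        agents = [ms.AgentState(0, "vorticella", "sessile", 50.0, 60.0,
                                0.0, 0.0, 13.0),
                  ms.AgentState(1, "zoospore", "encysted", 70.0, 80.0,
                                0.0, 0.0, 6.0)]
        for _ in range(20):
            agents = ms.step_agents(agents, field, None, 0.0735, rng,
                                    config=cfg)
        assert (agents[0].x, agents[0].y) == (50.0, 60.0)
        assert (agents[1].x, agents[1].y) == (70.0, 80.0)

    def test_vortex_advection_closed_circular_orbit(self):
        """A passive tracer in a feeding vortex orbits at constant radius."""
        cfg = small_config()
        field = make_field(cfg)
        flow = ms.FlowField(vortex_centers=[(130.0, 130.0)])
        models = ms.default_motion_models()
        models["bacterium"] = ms.SpeciesMotionModel(
            species="bacterium", speed_range=(0.0, 0.0),
            direction_model="brownian_advected", density=0.0,
            body_radius_range=(2.0, 2.0), rotational_diffusion=0.0)
        a = ms.AgentState(0, "bacterium", "swimming", 170.0, 130.0,
                          0.0, 0.0, 2.0)
        rng = np.random.default_rng(0)
        radii = []
        agents = [a]
        for _ in range(200):
            agents = ms.step_agents(agents, field, flow, 0.0735, rng,
                                    models=models, config=cfg)
            radii.append(math.hypot(agents[0].x - 130, agents[0].y - 130))
        assert np.ptp(radii) < 1e-9
        assert radii[0] == pytest.approx(40.0)

    def test_flow_speed_monotone_decay_and_cutoff(self):
        flow = ms.FlowField(vortex_centers=[(0.0, 0.0)])
        rs = np.linspace(1, 500, 200)
        vs = [flow.tangential_speed(r) for r in rs]
        assert all(a >= b - 1e-12 for a, b in zip(vs, vs[1:]))
        assert flow.tangential_speed(451.0) == 0.0

    def _zoospore_drift(self, strength, n=200, steps=100, seed=5):
        """Mean displacement along the source axis (negative = away)."""
        cfg = ms.ChamberConfig(rng_seed=0)
        field = ms.diffuse_concentration(cfg, 0.0)
        rng = np.random.default_rng(seed)
        import dataclasses
        models = ms.default_motion_models()
        models["zoospore"] = dataclasses.replace(
            models["zoospore"], chemotaxis_strength=strength,
            encystment_threshold=None)
        agents = [ms.AgentState(i, "zoospore", "swimming",
                                float(rng.uniform(100, 900)),
                                float(rng.uniform(250, 550)),
                                float(rng.uniform(-math.pi, math.pi)),
                                120.0, 6.0) for i in range(n)]
        start_y = np.array([a.y for a in agents])
        for k in range(steps):
            agents = ms.step_agents(agents, field, None, 0.0735, rng,
                                    models=models, t=k * 0.0735, config=cfg)
        # source on the top edge: moving away = increasing y, so the
        # projection on the source direction is -Δy
        proj = -(np.array([a.y for a in agents]) - start_y)
        return proj.mean(), proj.std() / math.sqrt(n)

    def test_negative_chemotaxis_drift(self):
        """Zoospore ensembles drift away from the potassium source."""
        mean, _ = self._zoospore_drift(strength=5.0)
        assert mean < 0

    def test_zero_chemotaxis_no_drift(self):
        mean, sem = self._zoospore_drift(strength=0.0)
        assert abs(mean) < 3 * sem

    def test_encystment_is_permanent_and_local(self):
        """Zoospores above the concentration threshold encyst and stop."""
        cfg = small_config(source_amount=100.0)
        field = ms.diffuse_concentration(cfg, 0.0)
        import dataclasses
        models = ms.default_motion_models()
        thr = field.value_at(130.0, 160.0)
        models["zoospore"] = dataclasses.replace(
            models["zoospore"], encystment_threshold=thr)
        near = ms.AgentState(0, "zoospore", "swimming", 130.0, 140.0,
                             0.0, 100.0, 6.0)
        far = ms.AgentState(1, "zoospore", "swimming", 20.0, 20.0,
                            0.0, 100.0, 6.0)
        rng = np.random.default_rng(0)
        out = ms.step_agents([near, far], field, None, 0.0735, rng,
                             models=models, config=cfg)
        assert out[0].mode == "encysted" and out[0].speed == 0.0
        assert out[1].mode == "swimming"
        out2 = ms.step_agents(out, field, None, 0.0735, rng,
                              models=models, config=cfg)
        assert out2[0].mode == "encysted"
        assert (out2[0].x, out2[0].y) == (130.0, 140.0)

    def test_nan_field_rejected(self):
        vals = np.ones((10, 10))
        vals[3, 3] = np.nan
        with pytest.raises(ValueError):
            ms.ConcentrationField(vals, 1.3)

    def test_reflecting_boundary(self):
        cfg = small_config()
        field = make_field(cfg)
        a = ms.AgentState(0, "vorticella", "swimming", 258.0, 130.0,
                          0.0, 500.0, 13.0)
        import dataclasses
        models = ms.default_motion_models()
        models["vorticella"] = dataclasses.replace(models["vorticella"],
                                                   sinusoid_amplitude=0.0)
        rng = np.random.default_rng(0)
        out = ms.step_agents([a], field, None, 0.0735, rng, models=models,
                             config=cfg)
        assert 0 <= out[0].x <= 260.0
        assert math.cos(out[0].heading) < 0  # bounced back


class TestRender:
    def test_empty_scene_single_intensity(self):
        cfg = small_config()
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
        stack, _ = ms.render_frames(truth, cfg, noise_sd=0.0)
        assert len(np.unique(stack)) == 1
        assert stack.shape == (cfg.n_frames, *cfg.shape)

    def test_single_sessile_vorticella_is_one_round_spot(self):
        """Noise-free render of one trophont segments to a single
        high-circularity component."""
        cfg = small_config(n_frames=1)
        truth = pd.DataFrame(
            [[1, 0, "vorticella", "sessile", 130.0, 130.0, 13.0, 0.0, 0.0]],
            columns=TRUTH_COLUMNS)
        stack, _ = ms.render_frames(truth, cfg, noise_sd=0.0)
        spots = ms.segment_stack(stack, 110, cfg.pixel_size)
        assert len(spots) == 1
        assert spots["circularity"].iloc[0] > 0.9

    def test_rendered_counts_match_truth(self, recovery_scene):
        """In an uncrowded frame region every agent yields pixels; total
        per-frame truth rows equal live agents."""
        truth = recovery_scene["sim"].truth
        per_frame = truth.groupby("frame").size()
        n_agents = truth["agent_id"].nunique()
        assert (per_frame == n_agents).all()

    def test_bit_identical_stacks_same_seed(self):
        cfg = small_config(n_frames=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = ms.simulate_scene(cfg).stack
            s2 = ms.simulate_scene(cfg).stack
        assert np.array_equal(s1, s2)

    def test_subpixel_bodies_rejected(self):
        cfg = small_config(pixel_size=5.0, field_width=250.0,
                           field_height=250.0)
        truth = pd.DataFrame(
            [[1, 0, "bacterium", "swimming", 100.0, 100.0, 1.0, 0.0, 5.0]],
            columns=TRUTH_COLUMNS)
        with pytest.raises(ValueError):
            ms.render_frames(truth, cfg, noise_sd=0.0)


class TestConfigValidation:
    def test_invalid_chamber_configs(self):
        with pytest.raises(ValueError):
            ms.ChamberConfig(pixel_size=0.0)
        with pytest.raises(ValueError):
            ms.ChamberConfig(source_position=(2000.0, 0.0))

    def test_speed_band_enforced(self):
        with pytest.raises(ValueError):
            ms.SpeciesMotionModel(species="bacterium",
                                  speed_range=(0.0, 100.0),
                                  direction_model="brownian_advected",
                                  density=10.0,
                                  body_radius_range=(1.5, 2.5))

    def test_sessile_speed_invariant(self):
        with pytest.raises(ValueError):
            ms.AgentState(0, "vorticella", "sessile", 0.0, 0.0, 0.0,
                          5.0, 13.0)
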