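"""Shared fixtures: seeded synthetic scenes run once per session.

All scenes are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

import microswarm as ms


@pytest.fixture(scope="session")
def recovery_scene():
    """150-frame default-density scene, no gradient, no vortices, noise-free.

    The controlled parameter-recovery condition: every agent keeps its
    configured speed, so ground-truth speeds are stationary.
    """
    cfg = ms.ChamberConfig(n_frames=150, source_amount=0.0, rng_seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = ms.simulate_scene(cfg, flow=ms.FlowField(vortex_centers=[]),
                                noise_sd=0.0)
        spots = ms.segment_stack(sim.stack, 110, cfg.pixel_size)
        labeled, counts = ms.partition_table(spots)
        tracks = ms.track_all_species(labeled, ms.default_rules())
        metrics = ms.compute_track_metrics(tracks, cfg.frame_interval)
    return {"config": cfg, "sim": sim, "spots": spots, "labeled": labeled,
            "counts": counts, "tracks": tracks, "metrics": metrics}


@pytest.fixture(scope="session")
def gradient_scene():
    """Default chamber with the potassium source active (136 frames)."""
    cfg = ms.ChamberConfig(rng_seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = ms.simulate_scene(cfg)
        spots = ms.segment_stack(sim.stack, 110, cfg.pixel_size)
        labeled, _ = ms.partition_table(spots)
        tracks = ms.track_all_species(labeled, ms.default_rules())
        metrics = ms.compute_track_metrics(tracks, cfg.frame_interval)
    return {"config": cfg, "sim": sim, "labeled": labeled,
            "tracks": tracks, "metrics": metrics}


@pytest.fixture(scope="session")
def vortex_scene():
    """Bacteria plus one sessile vorticella whose feeding vortex sits at
    (150, 150) µm; no potassium source."""
    cfg = ms.ChamberConfig(n_frames=100, source_amount=0.0, rng_seed=3)
    models = ms.default_motion_models()
    models["vorticella"] = dataclasses.replace(models["vorticella"],
                                               density=0.0)
    rng = np.random.default_rng(cfg.rng_seed)
    agents = ms.initialize_agents(cfg, models, rng)
    agents.append(ms.AgentState(10_000, "vorticella", "sessile",
                                150.0, 150.0, 0.0, 0.0, 13.0))
    flow = ms.FlowField(vortex_centers=[(150.0, 150.0)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = ms.simulate_scene(cfg, models=models, flow=flow, agents=agents)
        spots = ms.segment_stack(sim.stack, 110, cfg.pixel_size)
        labeled, _ = ms.partition_table(spots)
        tracks = ms.track_all_species(labeled, ms.default_rules())
        metrics = ms.compute_track_metrics(tracks, cfg.frame_interval,
                                           min_length=5)
    return {"config": cfg, "sim": sim, "tracks": tracks, "metrics": metrics,
            "flow": flow}


@pytest.fixture(scope="session")
def band_scene():
    """Scene whose body radii are drawn from disjoint bands
    (bacteria 1–2, zoospores 5–9, vorticellae 11–18 µm)."""
    models = ms.default_motion_models()
    models["zoospore"] = dataclasses.replace(
        models["zoospore"], body_radius_range=(5.0, 9.0), density=100.0)
    models["bacterium"] = dataclasses.replace(
        models["bacterium"], body_radius_range=(1.0, 2.0), density=300.0)
    models["vorticella"] = dataclasses.replace(
        models["vorticella"], body_radius_range=(11.0, 18.0), density=15.0)
    cfg = ms.ChamberConfig(n_frames=40, source_amount=0.0, rng_seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = ms.simulate_scene(cfg, models=models)
        spots = ms.segment_stack(sim.stack, 110, cfg.pixel_size)
        labeled, counts = ms.partition_table(spots)
    return {"config": cfg, "sim": sim, "labeled": labeled, "counts": counts}
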