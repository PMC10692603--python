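"""Agent-based simulator of a three-species microbial community in a 2-D
microchamber with a diffusing potassium point source.

The simulated community mirrors a mixed suspension of *Phytophthora*
zoospores, *Vorticella* ciliates and *Enterobacter* bacteria observed by
bright-field videomicroscopy:

* **zoospores** swim persistently, reorient away from the local potassium
  gradient (negative chemotaxis) and encyst irreversibly — shedding their
  flagella and stopping — where the concentration exceeds a threshold;
* **vorticellae** occur in two forms: sessile stalked trophonts (fixed,
  near-circular, each generating a feeding vortex) and free-swimming
  telotrochs (fast, elongated, ballistic with a sinusoidal heading wobble,
  indifferent to the gradient);
* **bacteria** perform a slow rotational-diffusion random walk and are
  additionally advected by the feeding vortices of sessile vorticellae.

The simulator renders 8-bit grayscale stacks (dark bodies on a bright
background, the pre-binarization analogue of the binary masks used in the
downstream analysis) and emits a ground-truth table so every later pipeline
stage can be validated against known identities and trajectories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("zoospore", "vorticella", "bacterium")
MODES = ("swimming", "sessile", "encysted")

#: aspect ratio (major/minor) of free-swimming vorticella ellipses
TELOTROCH_ASPECT = 3.0
#: rendered intensity of the background and of cell bodies (8-bit)
BACKGROUND_INTENSITY = 200.0
BODY_INTENSITY = 50.0

#: per-species plausibility bands for configured swimming speeds (µm/s)
SPEED_BANDS = {
    "zoospore": (0.0, 213.0),
    "vorticella": (0.0, 800.0),
    "bacterium": (0.0, 28.0),
}


@dataclass
class ChamberConfig:
    """Geometry, optics and source parameters of the imaged chamber region.

    Lengths are in µm, times in seconds.  The default field of view is
    1000×800 µm imaged at 1.3 µm/pixel with a 0.0735 s frame interval.  The
    potassium source sits on the top-edge midline; its release predates the
    first frame by ``pre_diffusion_time`` (default 300 s, i.e. imaging
    starts at the 5-minute time point).
    """

    field_width: float = 1000.0
    field_height: float = 800.0
    pixel_size: float = 1.3
    frame_interval: float = 0.0735
    n_frames: int = 136
    chamber_depth: float = 400.0
    source_position: tuple[float, float] = (500.0, 0.0)
    source_amount: float = 250.0
    diffusion_coefficient: float = 1000.0
    pre_diffusion_time: float = 300.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("field_width", "field_height", "pixel_size",
                     "frame_interval", "chamber_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.source_amount < 0:
            raise ValueError("source_amount must be >= 0")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be > 0")
        sx, sy = self.source_position
        if not (0 <= sx <= self.field_width and 0 <= sy <= self.field_height):
            raise ValueError("source_position must lie on or inside the field")

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (rows, cols) of the rendered stack."""
        return (int(round(self.field_height / self.pixel_size)),
                int(round(self.field_width / self.pixel_size)))

    @property
    def volume_ul(self) -> float:
        """Chamber volume under the field of view, in µl."""
        return (self.field_width * self.field_height * self.chamber_depth
                * 1e-9)


@dataclass
class SpeciesMotionModel:
    """Motion and behavior parameters of one species.

    ``speed_range`` (µm/s) bounds the per-agent swimming speed drawn at
    initialization; it must sit inside the species' plausibility band
    (zoospore 0–213, vorticella 0–800, bacterium 0–28 µm/s).  ``density``
    is in cells/µl and is scaled to the imaged chamber volume.
    """

    species: str
    speed_range: tuple[float, float]
    direction_model: str
    density: float
    body_radius_range: tuple[float, float]
    rotational_diffusion: float = 0.0
    chemotaxis_strength: float = 0.0
    encystment_threshold: float | None = None
    sessile_fraction: float = 0.0
    sinusoid_amplitude: float = 0.0
    sinusoid_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        lo, hi = self.speed_range
        blo, bhi = SPEED_BANDS[self.species]
        if not (blo <= lo <= hi <= bhi):
            raise ValueError(
                f"{self.species} speed_range {self.speed_range} outside "
                f"plausibility band {SPEED_BANDS[self.species]}")
        if self.chemotaxis_strength < 0:
            raise ValueError("chemotaxis_strength must be >= 0")
        if not 0 <= self.sessile_fraction <= 1:
            raise ValueError("sessile_fraction must be in [0, 1]")


def default_motion_models() -> dict[str, SpeciesMotionModel]:
    """Study-condition defaults for the three species.

    Densities follow the 200:10:2000 cells/µl calibration of the mixed
    suspension.  The zoospore encystment threshold equals the concentration
    at the contour enclosing roughly the nearest 20% of the default field
    at the start of imaging (default source, D = 1000 µm²/s, 300 s of
    pre-diffusion).
    """
    return {
        "zoospore": SpeciesMotionModel(
            species="zoospore",
            speed_range=(80.0, 160.0),
            direction_model="chemotactic_biased",
            density=200.0,
            body_radius_range=(5.0, 7.0),
            rotational_diffusion=1.0,
            chemotaxis_strength=5.0,
            encystment_threshold=6.1e-5,
        ),
        "vorticella": SpeciesMotionModel(
            species="vorticella",
            speed_range=(250.0, 600.0),
            direction_model="ballistic_sinusoidal",
            density=10.0,
            body_radius_range=(11.0, 15.0),
            sessile_fraction=0.4,
            sinusoid_amplitude=0.5,
            sinusoid_frequency=1.0,
        ),
        "bacterium": SpeciesMotionModel(
            species="bacterium",
            speed_range=(2.0, 12.0),
            direction_model="brownian_advected",
            density=2000.0,
            body_radius_range=(1.5, 2.5),
            rotational_diffusion=2.0,
        ),
    }


@dataclass
class FlowField:
    """Feeding-vortex flow generated by sessile vorticellae.

    The tangential speed induced by each vortex is constant
    (``vortex_strength / core_radius``) inside the core, decays as
    ``vortex_strength / r`` outside it and vanishes beyond
    ``influence_radius`` (default 450 µm, the reported reach of a single
    *Vorticella*).  Induced speed is therefore non-increasing with distance
    from the center.
    """

    vortex_centers: list[tuple[float, float]] = dc_field(default_factory=list)
    vortex_strength: float = 1200.0
    core_radius: float = 20.0
    influence_radius: float = 450.0

    def __post_init__(self) -> None:
        if self.vortex_strength < 0 or self.core_radius <= 0:
            raise ValueError("vortex_strength >= 0 and core_radius > 0 required")
        if self.influence_radius <= self.core_radius:
            raise ValueError("influence_radius must exceed core_radius")

    def tangential_speed(self, r: float) -> float:
        """Induced tangential speed (µm/s) at distance ``r`` from a center."""
        if r > self.influence_radius:
            return 0.0
        return self.vortex_strength / max(r, self.core_radius)

    def advect(self, x: float, y: float, dt: float) -> tuple[float, float]:
        """Rotate ``(x, y)`` about the nearest vortex center for time ``dt``.

        The rotation is exact (constant-radius circular orbit), so a
        passive tracer in the vortex never spirals in or out.
        """
        if not self.vortex_centers:
            return x, y
        cx, cy = min(self.vortex_centers,
                     key=lambda c: (x - c[0]) ** 2 + (y - c[1]) ** 2)
        dx, dy = x - cx, y - cy
        r = math.hypot(dx, dy)
        if r == 0.0 or r > self.influence_radius:
            return x, y
        dtheta = self.tangential_speed(r) * dt / r
        cos_t, sin_t = math.cos(dtheta), math.sin(dtheta)
        return (cx + dx * cos_t - dy * sin_t,
                cy + dx * sin_t + dy * cos_t)


@dataclass
class AgentState:
    """State of one simulated cell. Positions in µm, heading in radians."""

    agent_id: int
    species: str
    mode: str
    x: float
    y: float
    heading: float
    speed: float
    body_radius: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("sessile", "encysted") and self.speed != 0.0:
            raise ValueError(f"{self.mode} agents must have speed 0")


class ConcentrationField:
    """Scalar concentration field sampled on the image grid.

    Values live at pixel centers; ``value_at``/``gradient_at`` interpolate
    bilinearly at physical (µm) positions.
    """

    def __init__(self, values: np.ndarray, pixel_size: float):
        self.values = np.asarray(values, dtype=float)
        self.pixel_size = float(pixel_size)
        if self.values.ndim != 2:
            raise ValueError("concentration field must be 2-D")
        if np.isnan(self.values).any():
            raise ValueError("concentration field contains NaN")
        gy, gx = np.gradient(self.values, self.pixel_size)
        self._grad = (gx, gy)

    def _indices(self, x: float, y: float) -> tuple[float, float]:
        ny, nx = self.values.shape
        col = np.clip(x / self.pixel_size - 0.5, 0, nx - 1)
        row = np.clip(y / self.pixel_size - 0.5, 0, ny - 1)
        return row, col

    def _bilinear(self, arr: np.ndarray, x: float, y: float) -> float:
        row, col = self._indices(x, y)
        r0, c0 = int(row), int(col)
        r1 = min(r0 + 1, arr.shape[0] - 1)
        c1 = min(c0 + 1, arr.shape[1] - 1)
        fr, fc = row - r0, col - c0
        top = arr[r0, c0] * (1 - fc) + arr[r0, c1] * fc
        bot = arr[r1, c0] * (1 - fc) + arr[r1, c1] * fc
        return float(top * (1 - fr) + bot * fr)

    def value_at(self, x: float, y: float) -> float:
        return self._bilinear(self.values, x, y)

    def gradient_at(self, x: float, y: float) -> tuple[float, float]:
        gx, gy = self._grad
        return self._bilinear(gx, x, y), self._bilinear(gy, x, y)


def diffuse_concentration(config: ChamberConfig, t: float) -> ConcentrationField:
    """Closed-form 2-D point-source diffusion kernel on the image grid.

    C(x, t) = M / (4πD·te) · exp(−|x − x0|² / (4D·te)) with the effective
    time te = t + pre_diffusion_time, emulating passive dispersion of the
    potassium bolus from the lateral inlet.  ``t`` is time since the first
    frame; te must be strictly positive (the kernel is singular at te = 0).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    te = t + config.pre_diffusion_time
    if te <= 0:
        raise ValueError("effective diffusion time must be > 0 "
                         "(singular kernel at t + pre_diffusion_time = 0)")
    ny, nx = config.shape
    px = config.pixel_size
    if config.source_amount == 0:
        return ConcentrationField(np.zeros((ny, nx)), px)
    xs = (np.arange(nx) + 0.5) * px
    ys = (np.arange(ny) + 0.5) * px
    xx, yy = np.meshgrid(xs, ys)
    sx, sy = config.source_position
    r2 = (xx - sx) ** 2 + (yy - sy) ** 2
    d4t = 4.0 * config.diffusion_coefficient * te
    values = config.source_amount / (math.pi * d4t) * np.exp(-r2 / d4t)
    return ConcentrationField(values, px)


def _reflect(x: float, y: float, heading: float, config: ChamberConfig
             ) -> tuple[float, float, float]:
    """Mirror a position back into the chamber, flipping the heading."""
    w, h = config.field_width, config.field_height
    # at most a few reflections per step for realistic speeds
    for _ in range(8):
        moved = False
        if x < 0:
            x, heading, moved = -x, math.pi - heading, True
        elif x > w:
            x, heading, moved = 2 * w - x, math.pi - heading, True
        if y < 0:
            y, heading, moved = -y, -heading, True
        elif y > h:
            y, heading, moved = 2 * h - y, -heading, True
        if not moved:
            break
    return x, y, heading


def step_agents(agents: Sequence[AgentState],
                field: ConcentrationField,
                flow: FlowField | None,
                dt: float,
                rng: np.random.Generator,
                models: dict[str, SpeciesMotionModel] | None = None,
                t: float = 0.0,
                config: ChamberConfig | None = None) -> list[AgentState]:
    """Advance all agents by one time step ``dt``.

    Zoospores blend rotational diffusion with reorientation away from the
    local concentration gradient (probability 1 − exp(−strength·dt) per
    step) and encyst permanently where concentration exceeds the species
    threshold.  Free vorticellae move ballistically with a sinusoidal
    heading perturbation and ignore the gradient.  Bacteria random-walk and
    are advected by the vortex flow.  Sessile and encysted agents do not
    move.  Boundaries reflect.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if models is None:
        models = default_motion_models()
    if config is None:
        ny, nx = field.values.shape
        config = ChamberConfig(field_width=nx * field.pixel_size,
                               field_height=ny * field.pixel_size,
                               pixel_size=field.pixel_size)
    out: list[AgentState] = []
    for a in agents:
        if a.mode in ("sessile", "encysted"):
            out.append(replace(a))
            continue
        m = models[a.species]
        x, y, heading = a.x, a.y, a.heading
        if a.species == "zoospore":
            if (m.encystment_threshold is not None
                    and field.value_at(x, y) > m.encystment_threshold):
                out.append(replace(a, mode="encysted", speed=0.0))
                continue
            if m.rotational_diffusion > 0:
                heading += math.sqrt(2 * m.rotational_diffusion * dt) \
                    * rng.standard_normal()
            if m.chemotaxis_strength > 0:
                gx, gy = field.gradient_at(x, y)
                if gx != 0.0 or gy != 0.0:
                    p_reorient = 1.0 - math.exp(-m.chemotaxis_strength * dt)
                    if rng.random() < p_reorient:
                        heading = (math.atan2(-gy, -gx)
                                   + 0.3 * rng.standard_normal())
            x += a.speed * math.cos(heading) * dt
            y += a.speed * math.sin(heading) * dt
        elif a.species == "vorticella":
            eff = heading + m.sinusoid_amplitude * math.sin(
                2 * math.pi * m.sinusoid_frequency * t + a.phase)
            x += a.speed * math.cos(eff) * dt
            y += a.speed * math.sin(eff) * dt
        else:  # bacterium
            if m.rotational_diffusion > 0:
                heading += math.sqrt(2 * m.rotational_diffusion * dt) \
                    * rng.standard_normal()
            x += a.speed * math.cos(heading) * dt
            y += a.speed * math.sin(heading) * dt
            if flow is not None:
                x, y = flow.advect(x, y, dt)
        x, y, heading = _reflect(x, y, heading, config)
        out.append(replace(a, x=x, y=y, heading=heading))
    return out


def initialize_agents(config: ChamberConfig,
                      models: dict[str, SpeciesMotionModel],
                      rng: np.random.Generator) -> list[AgentState]:
    """Seed the chamber with agents at the configured densities.

    Counts are ``density × imaged chamber volume`` rounded to the nearest
    integer.  A ``sessile_fraction`` of vorticellae are pinned as sessile
    trophonts; everything else starts swimming with uniform random
    position, heading, speed and body radius.
    """
    agents: list[AgentState] = []
    aid = 0
    for sp in SPECIES:
        m = models[sp]
        n = int(round(m.density * config.volume_ul))
        n_sessile = int(round(n * m.sessile_fraction))
        for i in range(n):
            sessile = i < n_sessile
            speed = 0.0 if sessile else float(rng.uniform(*m.speed_range))
            agents.append(AgentState(
                agent_id=aid,
                species=sp,
                mode="sessile" if sessile else "swimming",
                x=float(rng.uniform(0, config.field_width)),
                y=float(rng.uniform(0, config.field_height)),
                heading=float(rng.uniform(-math.pi, math.pi)),
                speed=speed,
                body_radius=float(rng.uniform(*m.body_radius_range)),
                phase=float(rng.uniform(0, 2 * math.pi)),
            ))
            aid += 1
    return agents


TRUTH_COLUMNS = ["frame", "agent_id", "species", "mode",
                 "x_um", "y_um", "radius_um", "heading", "speed_ums"]


def _truth_frame(agents: Iterable[AgentState], frame: int) -> list[list]:
    return [[frame, a.agent_id, a.species, a.mode, a.x, a.y,
             a.body_radius, a.heading, a.speed] for a in agents]


def render_frames(truth: pd.DataFrame,
                  config: ChamberConfig,
                  noise_sd: float = 10.0,
                  rng: np.random.Generator | None = None
                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a ground-truth table into an 8-bit grayscale stack.

    Bodies are drawn dark (≈50) on a bright background (≈200) with
    area-sampled (anti-aliased) edges: each pixel's darkening is
    proportional to its estimated coverage by the body.  Zoospores, sessile
    vorticellae and bacteria are disks; free-swimming vorticellae are 3:1
    ellipses of the same area, oriented along the heading.  Gaussian noise
    of standard deviation ``noise_sd`` is added and the result clipped to
    [0, 255].  Returns the stack and the truth table with mirrored pixel
    coordinates (``x_px``, ``y_px``) appended.  Overlapping bodies merge
    into single blobs — a feature of crowded scenes, not an error.
    """
    ny, nx = config.shape
    px = config.pixel_size
    min_r = truth["radius_um"].min() if len(truth) else px
    if len(truth) and min_r / px < 0.5:
        raise ValueError(
            f"smallest body radius {min_r:.3g} µm is below half a pixel "
            f"({px} µm/px); bodies must span at least one pixel")
    frames = sorted(truth["frame"].unique()) if len(truth) else []
    n_frames = config.n_frames
    stack = np.full((n_frames, ny, nx), BACKGROUND_INTENSITY, dtype=float)
    amplitude = BACKGROUND_INTENSITY - BODY_INTENSITY
    for f in frames:
        sub = truth[truth["frame"] == f]
        canvas = stack[int(f) - 1]
        for rec in sub.itertuples(index=False):
            cx = rec.x_um / px - 0.5
            cy = rec.y_um / px - 0.5
            r = rec.radius_um / px
            if rec.species == "vorticella" and rec.mode == "swimming":
                a = r * math.sqrt(TELOTROCH_ASPECT)
                b = r / math.sqrt(TELOTROCH_ASPECT)
                _draw_ellipse(canvas, cx, cy, a, b, rec.heading, amplitude)
            else:
                _draw_disk(canvas, cx, cy, r, amplitude)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed + 7919)
        stack = stack + rng.normal(0.0, noise_sd, stack.shape)
    stack = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    truth_px = truth.copy()
    truth_px["x_px"] = truth_px["x_um"] / px - 0.5
    truth_px["y_px"] = truth_px["y_um"] / px - 0.5
    return stack, truth_px


def _draw_disk(canvas: np.ndarray, cx: float, cy: float, r: float,
               amplitude: float) -> None:
    ny, nx = canvas.shape
    r_ext = r + 1.0
    c0, c1 = max(0, int(cx - r_ext)), min(nx - 1, int(cx + r_ext) + 1)
    r0, r1 = max(0, int(cy - r_ext)), min(ny - 1, int(cy + r_ext) + 1)
    if c1 < c0 or r1 < r0:
        return
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    dx = cols[None, :] - cx
    dy = rows[:, None] - cy
    d = np.sqrt(dx * dx + dy * dy)
    coverage = np.clip(r - d + 0.5, 0.0, 1.0)
    region = canvas[r0:r1 + 1, c0:c1 + 1]
    np.minimum(region, BACKGROUND_INTENSITY - amplitude * coverage,
               out=region)


def _draw_ellipse(canvas: np.ndarray, cx: float, cy: float, a: float,
                  b: float, theta: float, amplitude: float) -> None:
    ny, nx = canvas.shape
    ext = a + 1.0
    c0, c1 = max(0, int(cx - ext)), min(nx - 1, int(cx + ext) + 1)
    r0, r1 = max(0, int(cy - ext)), min(ny - 1, int(cy + ext) + 1)
    if c1 < c0 or r1 < r0:
        return
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    dx = cols[None, :] - cx
    dy = rows[:, None] - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    dn = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # signed distance to the boundary approximated along the minor axis
    coverage = np.clip((1.0 - dn) * b + 0.5, 0.0, 1.0)
    region = canvas[r0:r1 + 1, c0:c1 + 1]
    np.minimum(region, BACKGROUND_INTENSITY - amplitude * coverage,
               out=region)


@dataclass
class SimulationResult:
    """Rendered stack plus ground truth of one simulated scene."""

    stack: np.ndarray
    truth: pd.DataFrame
    config: ChamberConfig
    models: dict[str, SpeciesMotionModel]
    flow: FlowField


def simulate_scene(config: ChamberConfig,
                   models: dict[str, SpeciesMotionModel] | None = None,
                   flow: FlowField | None = None,
                   noise_sd: float = 10.0,
                   agents: list[AgentState] | None = None
                   ) -> SimulationResult:
    """Run the agent-based model and render the full image stack.

    A single generator seeded from ``config.rng_seed`` drives every
    stochastic step (initial placement, motion noise, rendering noise), so
    identical configs yield bit-identical stacks.  If no flow field is
    given, one vortex is placed at each sessile vorticella.  Explicit
    ``agents`` override the density-based random initialization (useful
    for controlled scenes).
    """
    if models is None:
        models = default_motion_models()
    rng = np.random.default_rng(config.rng_seed)
    if agents is None:
        agents = initialize_agents(config, models, rng)
    if flow is None:
        centers = [(a.x, a.y) for a in agents
                   if a.species == "vorticella" and a.mode == "sessile"]
        flow = FlowField(vortex_centers=centers)
    dt = config.frame_interval
    records: list[list] = []
    for k in range(config.n_frames):
        t = k * dt
        conc = diffuse_concentration(config, t)
        records.extend(_truth_frame(agents, k + 1))
        if k < config.n_frames - 1:
            agents = step_agents(agents, conc, flow, dt, rng,
                                 models=models, t=t, config=config)
    truth = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    stack, truth_px = render_frames(truth, config, noise_sd=noise_sd, rng=rng)
    if logger.isEnabledFor(logging.DEBUG):
        n_enc = (truth[truth["frame"] == truth["frame"].max()]["mode"]
                 == "encysted").sum()
        logger.debug("simulated %d agents over %d frames (%d encysted at end)",
                     truth["agent_id"].nunique(), config.n_frames, n_enc)
    return SimulationResult(stack=stack, truth=truth, config=config,
                            models=models, flow=flow)
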