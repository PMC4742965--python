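"""Agent-based run-and-reverse gliding-motility simulator.

Raphid diatoms glide back and forth along their raphe: straight runs end
in stops at which the cell usually reverses direction. The walker here is
that pattern plus two couplings to a chemical field around a bead source:

* **klinokinesis / run-length bias** — the run-termination hazard is
  ``λ_stop = λ0 · exp(−κ·u)`` where ``u ∈ [−1, 1]`` is the cosine of the
  angle between the heading and the inward (up-gradient) radial direction.
  ``κ > 0`` prolongs up-gradient runs (attractant), ``κ < 0`` shortens
  them (repellent), ``κ = 0`` is the null walk. Turning itself is never
  biased — net drift emerges purely from run-length modulation.
* **chemokinesis** — gliding speed is elevated by a factor ``(1 + g)``
  when the cell senses no dissolved nutrient, relaxing toward the base
  speed as the local concentration rises (Michaelis-type relaxation with
  half-saturation ``CHEMOKINESIS_C_HALF``).

Headings additionally diffuse with intensity σ_θ (rad/√s) so 2-D dispersal
is non-degenerate. The arena boundary and the bead surface both reflect.
All randomness flows from a single seeded generator, so a run is exactly
reproducible from its config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gradient import PointSourceGradient, concentration_at_um
from .tracks import BeadAssayGeometry, TrackSet, trackset_from_arrays

#: Local concentration (μM) at which the chemokinetic speed boost is halved.
CHEMOKINESIS_C_HALF = 20.0

SCENARIOS = ("control", "attractant", "repellent", "starved", "replete")


@dataclass(frozen=True)
class WalkerParams:
    """Behavioural parameters of one simulated cell population.

    base_speed: gliding speed s0 in μm/s under nutrient-replete sensing.
    stop_rate: baseline run-termination hazard λ0 in 1/s.
    reversal_prob: probability q that a stop reverses the heading.
    heading_noise: rotational diffusion σ_θ in rad/√s.
    gradient_bias: κ, dimensionless; >0 attractant, <0 repellent, 0 null.
    chemokinesis_gain: g, fractional speed increase at zero local nutrient.
    """

    base_speed: float = 2.3
    stop_rate: float = 0.105
    reversal_prob: float = 0.8
    heading_noise: float = 0.3
    gradient_bias: float = 0.0
    chemokinesis_gain: float = 0.0

    def __post_init__(self) -> None:
        vals = (
            self.base_speed,
            self.stop_rate,
            self.reversal_prob,
            self.heading_noise,
            self.gradient_bias,
            self.chemokinesis_gain,
        )
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all walker parameters must be finite")
        if self.base_speed <= 0:
            raise ValueError("base_speed must be > 0")
        if self.stop_rate <= 0:
            raise ValueError("stop_rate must be > 0")
        if not 0.0 <= self.reversal_prob <= 1.0:
            raise ValueError("reversal_prob must be in [0, 1]")
        if self.heading_noise < 0:
            raise ValueError("heading_noise must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Arena, sampling and population-size settings of one simulated assay."""

    geometry: BeadAssayGeometry = field(default_factory=BeadAssayGeometry)
    gradient: PointSourceGradient | None = None
    arena_radius: float = 500.0
    dt: float = 0.1
    duration: float = 600.0
    n_cells: int = 200
    frame_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.arena_radius <= self.geometry.bead_radius:
            raise ValueError("arena_radius must exceed the bead radius")
        if self.frame_interval < self.dt:
            raise ValueError("frame_interval must be >= dt")


def scenario_params(scenario: str) -> WalkerParams:
    """Preset walker parameters for the study's experimental arms.

    control — blank bead, no bias; attractant — dSi-like bead, runs up the
    gradient prolonged; repellent — dGe-like bead, runs up the gradient cut
    short; starved / replete — chemokinesis presets whose mean gliding
    speeds differ by more than a factor of two.
    """
    base = WalkerParams()
    presets = {
        "control": base,
        "attractant": replace(base, gradient_bias=1.5),
        "repellent": replace(base, gradient_bias=-1.5),
        "starved": replace(base, base_speed=1.0, chemokinesis_gain=1.5),
        "replete": replace(base, base_speed=1.0),
    }
    if scenario not in presets:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {', '.join(SCENARIOS)}")
    return presets[scenario]


def _reflect(pos: np.ndarray, heading: np.ndarray, centre: np.ndarray,
             radius: float, outside: bool) -> None:
    """Reflect positions and headings at a circle, in place.

    ``outside=True`` folds points with ρ > radius back inside (arena wall);
    ``outside=False`` folds points with ρ < radius back outside (bead
    surface). The velocity's radial component is mirrored.
    """
    rel = pos - centre
    rho = np.hypot(rel[:, 0], rel[:, 1])
    hit = rho > radius if outside else (rho < radius) & (rho > 0)
    if not np.any(hit):
        return
    n = rel[hit] / rho[hit, None]
    pos[hit] = centre + n * (2 * radius - rho[hit])[:, None]
    v = np.column_stack([np.cos(heading[hit]), np.sin(heading[hit])])
    v -= 2 * np.sum(v * n, axis=1)[:, None] * n
    heading[hit] = np.arctan2(v[:, 1], v[:, 0])


def simulate_tracks(config: SimulationConfig, params: WalkerParams) -> TrackSet:
    """Run the walker population and return frame-sampled tracks.

    Integration uses the internal time step ``config.dt``; positions are
    recorded every ``config.frame_interval`` (the camera frame rate), so
    reported step speeds carry the same sampling bias as real tracking
    data. Initial positions are uniform over the annulus between the bead
    surface and the arena wall; initial headings are isotropic.
    """
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    centre = np.array([geom.bead_x, geom.bead_y])
    n = config.n_cells
    dt = config.dt

    # uniform over the annulus [bead_radius, arena_radius]
    u = rng.random(n)
    rho0 = np.sqrt(u * (config.arena_radius**2 - geom.bead_radius**2) + geom.bead_radius**2)
    phi0 = rng.uniform(0, 2 * math.pi, n)
    pos = centre + np.column_stack([rho0 * np.cos(phi0), rho0 * np.sin(phi0)])
    heading = rng.uniform(0, 2 * math.pi, n)

    n_steps = int(round(config.duration / dt))
    sample_every = int(round(config.frame_interval / dt))
    n_frames = n_steps // sample_every + 1
    out = np.empty((n, n_frames, 2))
    out[:, 0] = pos
    frame_times = np.arange(n_frames) * config.frame_interval

    sigma = params.heading_noise * math.sqrt(dt)
    has_gradient = config.gradient is not None

    for step in range(1, n_steps + 1):
        if sigma > 0:
            heading += rng.normal(0.0, sigma, n)

        rel = centre - pos
        rho = np.hypot(rel[:, 0], rel[:, 1])
        rho = np.maximum(rho, 1e-9)
        # u = cosine between heading and the inward radial (up-gradient) direction
        upgrad = (rel[:, 0] * np.cos(heading) + rel[:, 1] * np.sin(heading)) / rho

        if has_gradient and params.gradient_bias != 0.0:
            hazard = params.stop_rate * np.exp(-params.gradient_bias * upgrad)
        else:
            hazard = np.full(n, params.stop_rate)
        stopped = rng.random(n) < -np.expm1(-hazard * dt)
        reverse = stopped & (rng.random(n) < params.reversal_prob)
        heading[reverse] += math.pi

        if has_gradient and params.chemokinesis_gain != 0.0:
            c_local = concentration_at_um(config.gradient, rho)
            relax = 1.0 / (1.0 + c_local / CHEMOKINESIS_C_HALF)
            speed = params.base_speed * (1.0 + params.chemokinesis_gain * relax)
        elif params.chemokinesis_gain != 0.0:
            speed = params.base_speed * (1.0 + params.chemokinesis_gain)
        else:
            speed = params.base_speed

        pos[:, 0] += speed * dt * np.cos(heading)
        pos[:, 1] += speed * dt * np.sin(heading)

        _reflect(pos, heading, centre, config.arena_radius, outside=True)
        if geom.bead_radius > 0:
            _reflect(pos, heading, centre, geom.bead_radius, outside=False)

        if step % sample_every == 0:
            out[:, step // sample_every] = pos

    ids = [f"cell_{i:04d}" for i in range(n)]
    return trackset_from_arrays(ids, frame_times, out, frame_interval=config.frame_interval)
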