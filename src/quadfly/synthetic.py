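"""Agent-based synthetic data with known ground truth.

Every input the analysis pipeline consumes can be generated here: fly
trajectories in the four-quadrant arena, a deposited-pheromone field with
first-order evaporation, egg positions, spike trains and EAG-like traces,
and rendered infrared-style video frames.  The generator emulates the live
assay's study conditions -- 40-50 starved flies walking in a 19.5 cm
star-shaped arena filmed at 30 frames/s, a 5-min food-odor stimulation
followed by clean air and a 90-degree arena rotation, 23-hr egg-laying
recordings at 1 frame per 5 s -- while keeping the ground truth (which
agent went where, the region weights behind every egg, the true firing
rates behind every spike train) available for testing.

Motion model
------------
Discrete-time correlated random walk.  At each step an agent draws a
perturbation angle from a von Mises distribution whose mean points toward
the local attractant and whose concentration is ``beta * s``, where
``beta`` is the bias strength and ``s`` in [0, 1] the normalized local
stimulus strength; the new heading is the direction of

    persistence * u(heading) + (1 - persistence) * u(perturbation)

with ``u`` the unit vector of an angle.  At ``beta * s = 0`` the von Mises
collapses to the uniform circular distribution, so the walk is isotropic
and any measured attraction is attributable to the bias term alone; the
concentration parameter makes attraction strength graded in ``beta``
rather than all-or-none.  Stimulus strength: during an odor phase the
plume fills its quadrant uniformly, so agents outside it get ``s = 1``
toward the quadrant centroid and agents inside get no directional cue
(``s = 0``); during clean-air phases ``s`` is a saturating function of
the local deposited-pheromone gradient, followed uphill.

Pheromone field
---------------
A grid of deposited mass over the arena.  Per step of length ``dt`` each
cell decays by ``exp(-k * temperature_factor * dt)`` (first-order
evaporation; ``temperature_factor > 1`` models the heat sensitivity of the
deposit) and gains ``d * dt`` per male agent in the cell -- deposition is
male-only and active only while a food-odor phase is on and the cell lies
in the odor quadrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

from .ephys import SpikeTrain
from .geometry import ArenaGeometry, Quadrant, assign_quadrants, quadrant_centroid
from .tracking import Track, TrackSet

__all__ = [
    "EggLayingConfig",
    "Phase",
    "PheromoneField",
    "PostStimulusRun",
    "SimulationConfig",
    "SpikeTrainConfig",
    "ThreeWellPlate",
    "render_frames",
    "run_post_stimulus_protocol",
    "simulate_eag_trace",
    "simulate_eggs",
    "simulate_flies",
    "simulate_spike_train",
    "step_pheromone",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Phase:
    """One protocol epoch: 'pre' (no signal), 'stimulus' (odor on) or
    'clean_air' (odor off; agents may follow the deposited field)."""

    name: str
    duration: float
    odor_quadrant: Quadrant | None = None
    odor_is_food: bool = False

    def __post_init__(self) -> None:
        if self.name not in ("pre", "stimulus", "clean_air"):
            raise ValueError(f"unknown phase name {self.name!r}")
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if self.name == "stimulus" and self.odor_quadrant is None:
            raise ValueError("stimulus phase needs an odor_quadrant")


@dataclass(frozen=True)
class SimulationConfig:
    """Arena-walker simulation parameters.

    Defaults are the behavioral study conditions: 45 flies (half male),
    30 frames/s.  ``turn_persistence`` in [0, 1) weights the previous
    heading; ``bias_strength`` (beta >= 0) scales attraction, with beta = 0
    giving an isotropic walk.  ``step_speed_mean`` is mean walking speed in
    cm/s.  ``pheromone_gradient_scale`` (units/cm) is the gradient
    magnitude at which pheromone following reaches half saturation.
    """

    n_flies: int = 45
    frame_rate: float = 30.0
    phases: tuple[Phase, ...] = (Phase("pre", 300.0),)
    sex_of_agents: tuple[str, ...] | None = None
    step_speed_mean: float = 1.5
    turn_persistence: float = 0.7
    bias_strength: float = 2.0
    pheromone_gradient_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 0:
            raise ValueError("n_flies must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.phases:
            raise ValueError("at least one phase is required")
        if not (0 <= self.turn_persistence < 1):
            raise ValueError("turn_persistence must be in [0, 1)")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        if self.sex_of_agents is not None:
            if len(self.sex_of_agents) != self.n_flies:
                raise ValueError("sex_of_agents length must equal n_flies")
            bad = set(self.sex_of_agents) - {"male", "female"}
            if bad:
                raise ValueError(f"unknown sexes: {bad}")

    @property
    def duration(self) -> float:
        return sum(p.duration for p in self.phases)

    @property
    def sexes(self) -> tuple[str, ...]:
        """Agent sexes; default is a 1:1 male:female split."""
        if self.sex_of_agents is not None:
            return tuple(self.sex_of_agents)
        half = (self.n_flies + 1) // 2
        return tuple(
            "male" if i < half else "female" for i in range(self.n_flies)
        )


@dataclass
class PheromoneField:
    """Deposited-pheromone mass on a grid over the arena.

    ``grid`` is (rows, cols) in image orientation at the arena's pixel
    resolution; masses are arbitrary units, always >= 0.  ``evaporation_rate``
    k (1/s) gives first-order decay; the default 1/900 s^-1 e-folds the
    deposit in 15 min so that simulated post-stimulus attraction fades over
    tens of minutes.  ``deposit_rate`` d is units per male agent per s.
    ``temperature_factor`` multiplies k (> 1 models a heated arena).
    """

    grid: np.ndarray
    arena: ArenaGeometry
    evaporation_rate: float = 1.0 / 900.0
    deposit_rate: float = 1.0
    temperature_factor: float = 1.0
    plume_sigma_cm: float = 1.5
    _cache_version: int = field(default=-1, repr=False, compare=False)
    _cache_total: float = field(default=0.0, repr=False, compare=False)
    _cache_smoothed: np.ndarray | None = field(default=None, repr=False, compare=False)
    _version: int = field(default=0, repr=False, compare=False)

    @classmethod
    def for_arena(cls, arena: ArenaGeometry, **kwargs) -> "PheromoneField":
        return cls(grid=np.zeros(arena.image_shape), arena=arena, **kwargs)

    @property
    def total_mass(self) -> float:
        return float(self.grid.sum())

    def sensed_grid(self) -> np.ndarray:
        """Airborne concentration agents actually sense: the deposit grid
        smoothed by a Gaussian plume of ``plume_sigma_cm`` (deposited
        trails are one cell wide; the volatile radiates around them).
        Uniform decay only rescales the cached smoothed field."""
        if self.plume_sigma_cm <= 0:
            return self.grid
        total = self.total_mass
        if self._cache_version == self._version and self._cache_smoothed is not None:
            if total == self._cache_total:
                return self._cache_smoothed
            if self._cache_total > 0:  # pure decay since caching: rescale
                return self._cache_smoothed * (total / self._cache_total)
        from scipy.ndimage import gaussian_filter

        smoothed = gaussian_filter(
            self.grid, sigma=self.plume_sigma_cm * self.arena.px_per_cm
        )
        object.__setattr__(self, "_cache_version", self._version)
        object.__setattr__(self, "_cache_total", total)
        object.__setattr__(self, "_cache_smoothed", smoothed)
        return smoothed

    def _grid_coords(self, x: np.ndarray, y: np.ndarray):
        row, col = self.arena.cm_to_px(x, y)
        # sample at cell centers
        return np.asarray(row) - 0.5, np.asarray(col) - 0.5

    def _interp(self, grid: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r, c = self._grid_coords(np.asarray(x, float), np.asarray(y, float))
        nr, nc = grid.shape
        r = np.clip(r, 0, nr - 1)
        c = np.clip(c, 0, nc - 1)
        r0 = np.clip(np.floor(r).astype(int), 0, nr - 2)
        c0 = np.clip(np.floor(c).astype(int), 0, nc - 2)
        fr, fc = r - r0, c - c0
        return (
            grid[r0, c0] * (1 - fr) * (1 - fc)
            + grid[r0 + 1, c0] * fr * (1 - fc)
            + grid[r0, c0 + 1] * (1 - fr) * fc
            + grid[r0 + 1, c0 + 1] * fr * fc
        )

    def interpolate(
        self, x: np.ndarray, y: np.ndarray, sensed: bool = False
    ) -> np.ndarray:
        """Bilinear interpolation at physical positions (cm); ``sensed=True``
        samples the plume-smoothed field instead of the raw deposit grid."""
        grid = self.sensed_grid() if sensed else self.grid
        return self._interp(grid, x, y)

    def gradient(self, x: np.ndarray, y: np.ndarray, sensed: bool = True):
        """Gradient (d/dx, d/dy in units/cm) of the sensed (plume-smoothed)
        field by central differences; ``sensed=False`` uses the raw grid."""
        grid = self.sensed_grid() if sensed else self.grid
        h = 0.5 / self.arena.px_per_cm  # half a cell in cm
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        gx = (self._interp(grid, x + h, y) - self._interp(grid, x - h, y)) / (2 * h)
        gy = (self._interp(grid, x, y + h) - self._interp(grid, x, y - h)) / (2 * h)
        return gx, gy

    def occupancy_grid(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-cell count of agents at physical positions (cm)."""
        row, col = self.arena.cm_to_px(np.asarray(x, float), np.asarray(y, float))
        nr, nc = self.grid.shape
        r = np.clip(np.floor(row).astype(int), 0, nr - 1)
        c = np.clip(np.floor(col).astype(int), 0, nc - 1)
        counts = np.zeros_like(self.grid)
        np.add.at(counts, (r, c), 1.0)
        return counts

    def quadrant_mask(self, quadrant: Quadrant) -> np.ndarray:
        """Boolean grid of cells whose centers lie in ``quadrant``."""
        nr, nc = self.grid.shape
        rows, cols = np.meshgrid(
            np.arange(nr) + 0.5, np.arange(nc) + 0.5, indexing="ij"
        )
        x, y = self.arena.px_to_cm(rows, cols)
        labels = assign_quadrants(x.ravel(), y.ravel(), self.arena).reshape(nr, nc)
        return labels == quadrant.index


def step_pheromone(
    f: PheromoneField,
    male_occupancy: np.ndarray,
    odor_on: bool,
    dt: float,
    odor_mask: np.ndarray | None = None,
) -> PheromoneField:
    """Advance the field one step of length ``dt`` (s), in place.

    Each cell decays by ``exp(-k * temperature_factor * dt)``; deposition
    ``d * dt`` per male agent applies only while ``odor_on`` and, if an
    ``odor_mask`` is given, only in masked cells.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if male_occupancy.shape != f.grid.shape:
        raise ValueError("male_occupancy shape must match the field grid")
    f.grid *= math.exp(-f.evaporation_rate * f.temperature_factor * dt)
    if odor_on:
        deposit = f.deposit_rate * dt * male_occupancy
        if odor_mask is not None:
            deposit = deposit * odor_mask
        if deposit.any():
            f.grid += deposit
            f._version += 1  # structure changed: invalidate the plume cache
    return f


# ---------------------------------------------------------------------------
# arena walkers
# ---------------------------------------------------------------------------

def _convex_halfplanes(poly: Polygon):
    """Outward half-planes (n, b) with n.x <= b inside, for a convex CCW
    polygon; None if the polygon is not convex."""
    hull = poly.convex_hull
    if abs(hull.area - poly.area) > 1e-9 * max(poly.area, 1.0):
        return None
    xy = np.asarray(poly.exterior.coords)[:-1]
    if Polygon(xy).exterior.is_ccw is False:
        xy = xy[::-1]
    normals, offsets = [], []
    for i in range(len(xy)):
        p, q = xy[i], xy[(i + 1) % len(xy)]
        e = q - p
        n = np.array([e[1], -e[0]])  # outward for CCW
        n = n / np.linalg.norm(n)
        normals.append(n)
        offsets.append(float(n @ p))
    return np.asarray(normals), np.asarray(offsets)


def _reflect_into_convex(pos: np.ndarray, normals, offsets, max_iter: int = 8):
    """Specular reflection of points into the convex region n.x <= b."""
    for _ in range(max_iter):
        viol = pos @ normals.T - offsets[None, :]  # (n_pts, n_edges)
        worst = viol.max(axis=1)
        outside = worst > 0
        if not outside.any():
            break
        edge = viol.argmax(axis=1)
        d = worst[outside]
        n = normals[edge[outside]]
        pos[outside] -= 2 * d[:, None] * n
    return pos


def _uniform_in_mask(rng: np.random.Generator, arena: ArenaGeometry, n: int):
    """Rejection-sample n points uniform over the walkable mask."""
    from shapely import contains_xy

    poly = arena.mask
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        ok = contains_xy(poly, x, y)
        k = min(int(ok.sum()), n - filled)
        out[filled : filled + k, 0] = x[ok][:k]
        out[filled : filled + k, 1] = y[ok][:k]
        filled += k
    return out


def simulate_flies(
    config: SimulationConfig,
    arena: ArenaGeometry,
    pheromone: PheromoneField | None = None,
    initial_positions: np.ndarray | None = None,
) -> TrackSet:
    """Simulate fly agents in the arena; returns one ground-truth track per
    agent, sampled at ``config.frame_rate``.

    If a ``pheromone`` field is given it is both read (clean-air attraction
    up the local gradient) and written in place (male-only deposition into
    the odor quadrant during food-odor stimulus phases).  All randomness
    descends from ``config.seed`` through one seeded generator consumed in
    a fixed agent order, so identical config and seed reproduce the tracks
    bitwise.
    """
    if pheromone is not None and pheromone.grid.shape != arena.image_shape:
        raise ValueError("pheromone grid does not match the arena resolution")
    n_steps = int(round(config.frame_rate * config.duration))
    if n_steps == 0:
        raise ValueError("zero-duration simulation")
    n = config.n_flies
    dt = 1.0 / config.frame_rate
    sexes = config.sexes
    male = np.array([s == "male" for s in sexes], dtype=bool)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if n == 0:
        return TrackSet(tracks=[], frame_rate=config.frame_rate, arena=arena)

    if initial_positions is not None:
        pos = np.asarray(initial_positions, float).copy()
        if pos.shape != (n, 2):
            raise ValueError("initial_positions must be (n_flies, 2)")
    else:
        pos = _uniform_in_mask(rng, arena, n)
    heading = rng.uniform(-np.pi, np.pi, n)

    halfplanes = _convex_halfplanes(arena.mask)

    # phase lookup per step
    edges = np.cumsum([p.duration for p in config.phases])
    step_t = (np.arange(n_steps)) * dt
    phase_idx = np.searchsorted(edges, step_t, side="right")
    phase_idx = np.clip(phase_idx, 0, len(config.phases) - 1)

    odor_masks: dict[Quadrant, np.ndarray] = {}
    traj = np.empty((n_steps, n, 2))
    persistence = config.turn_persistence
    beta = config.bias_strength
    g0 = config.pheromone_gradient_scale

    for t in range(n_steps):
        traj[t] = pos
        ph = config.phases[phase_idx[t]]

        # attractant direction and von Mises concentration per agent
        mu = np.zeros(n)
        kappa = np.zeros(n)
        if ph.name == "stimulus" and ph.odor_quadrant is not None and beta > 0:
            # The plume fills its quadrant uniformly: only agents outside it
            # get a directional cue (toward the quadrant centroid); inside,
            # s = 0 and the walk is locally unbiased, so occupancy stays
            # graded in beta instead of collapsing onto the centroid.
            cx, cy = quadrant_centroid(ph.odor_quadrant, arena)
            outside = (
                assign_quadrants(pos[:, 0], pos[:, 1], arena)
                != ph.odor_quadrant.index
            )
            mu = np.arctan2(cy - pos[:, 1], cx - pos[:, 0])
            kappa = beta * outside.astype(float)
        elif ph.name == "clean_air" and pheromone is not None and beta > 0:
            gx, gy = pheromone.gradient(pos[:, 0], pos[:, 1])
            gn = np.hypot(gx, gy)
            mu = np.arctan2(gy, gx)
            kappa = beta * gn / (gn + g0)

        perturb = rng.vonmises(mu, kappa)
        w = 1.0 - persistence
        vx = persistence * np.cos(heading) + w * np.cos(perturb)
        vy = persistence * np.sin(heading) + w * np.sin(perturb)
        base = np.where((vx == 0) & (vy == 0), heading, np.arctan2(vy, vx))
        heading = base

        step = rng.gamma(4.0, config.step_speed_mean / 4.0, n) * dt
        new = pos + np.column_stack([np.cos(heading) * step, np.sin(heading) * step])
        if halfplanes is not None:
            new = _reflect_into_convex(new, *halfplanes)
        else:  # non-convex custom mask: reject moves that leave it
            from shapely import contains_xy

            ok = contains_xy(arena.mask, new[:, 0], new[:, 1])
            new[~ok] = pos[~ok]
            heading[~ok] += np.pi
        moved = new - pos
        mn = np.hypot(moved[:, 0], moved[:, 1])
        has_moved = mn > 1e-12
        heading = np.where(
            has_moved, np.arctan2(moved[:, 1], moved[:, 0]), heading
        )
        pos = new

        # deposition during food-odor stimulation: male agents only
        if (
            pheromone is not None
            and ph.name == "stimulus"
            and ph.odor_is_food
            and male.any()
        ):
            if ph.odor_quadrant not in odor_masks:
                odor_masks[ph.odor_quadrant] = pheromone.quadrant_mask(
                    ph.odor_quadrant
                )
            occ = pheromone.occupancy_grid(pos[male, 0], pos[male, 1])
            step_pheromone(
                pheromone, occ, True, dt, odor_mask=odor_masks[ph.odor_quadrant]
            )
        elif pheromone is not None:
            step_pheromone(pheromone, np.zeros_like(pheromone.grid), False, dt)

    tracks = [
        Track(id=i, start_frame=0, xy=traj[:, i, :], sex=sexes[i])
        for i in range(n)
    ]
    return TrackSet(tracks=tracks, frame_rate=config.frame_rate, arena=arena)


# ---------------------------------------------------------------------------
# post-stimulus protocol (stimulate -> deposit -> rotate -> clean air)
# ---------------------------------------------------------------------------

@dataclass
class PostStimulusRun:
    """Outcome of a stimulate/rotate/clean-air protocol run.

    ``stimulus_ts`` are depositor tracks during odor-on; ``post_ts`` are
    detector tracks in the rotated arena under clean air; ``odor_quadrant``
    is the label during stimulation and ``remapped_quadrant`` where that
    physical region sits after rotation.
    """

    stimulus_ts: TrackSet
    post_ts: TrackSet
    field: PheromoneField
    odor_quadrant: Quadrant
    remapped_quadrant: Quadrant
    rotation_applied: int


def run_post_stimulus_protocol(
    arena: ArenaGeometry,
    seed: int,
    n_depositors: int = 20,
    n_detectors: int = 20,
    depositor_sexes: str = "mixed",
    stimulus_duration: float = 300.0,
    post_duration: float = 300.0,
    odor_quadrant: Quadrant = Quadrant.Q1,
    rotation: int = 90,
    frame_rate: float = 30.0,
    bias_strength: float = 2.0,
    temperature_factor: float = 1.0,
    clean_air_delay: float = 0.0,
    **sim_kwargs,
) -> PostStimulusRun:
    """Run the full post-stimulus aggregation protocol on synthetic agents.

    Depositor flies are stimulated with a food odor for
    ``stimulus_duration`` s (males deposit pheromone into the odor
    quadrant); the arena -- and the pheromone-bearing plate with it -- is
    then rotated by ``rotation`` degrees CCW, and naive detector flies walk
    under clean air for ``post_duration`` s, attracted only by the
    deposited field.  ``clean_air_delay`` evaporates the field for that
    many seconds between rotation and the detector phase.
    ``depositor_sexes`` is 'mixed', 'male' or 'female'.
    """
    if depositor_sexes == "mixed":
        sexes = None
    elif depositor_sexes in ("male", "female"):
        sexes = (depositor_sexes,) * n_depositors
    else:
        raise ValueError(f"unknown depositor_sexes {depositor_sexes!r}")

    field = PheromoneField.for_arena(arena, temperature_factor=temperature_factor)
    stim_cfg = SimulationConfig(
        n_flies=n_depositors,
        frame_rate=frame_rate,
        phases=(Phase("stimulus", stimulus_duration, odor_quadrant, odor_is_food=True),),
        sex_of_agents=sexes,
        bias_strength=bias_strength,
        seed=seed,
        **sim_kwargs,
    )
    stim_ts = simulate_flies(stim_cfg, arena, pheromone=field)

    from .geometry import remap_quadrant, rotate_arena

    # Rotating the arena relabels the quadrants relative to the plate; the
    # recorded coordinate frame follows the plate, so the deposit grid is
    # unchanged and the deposit region's label becomes the remapped one.
    arena_rot = rotate_arena(arena, rotation)
    field_rot = replace(field, arena=arena_rot)
    if clean_air_delay > 0:
        step_pheromone(
            field_rot, np.zeros_like(field_rot.grid), False, clean_air_delay
        )
    remapped = remap_quadrant(odor_quadrant, rotation)

    post_cfg = SimulationConfig(
        n_flies=n_detectors,
        frame_rate=frame_rate,
        phases=(Phase("clean_air", post_duration),),
        bias_strength=bias_strength,
        seed=seed + 1,
        **sim_kwargs,
    )
    post_ts = simulate_flies(post_cfg, arena_rot, pheromone=field_rot)
    return PostStimulusRun(
        stimulus_ts=stim_ts,
        post_ts=post_ts,
        field=field_rot,
        odor_quadrant=odor_quadrant,
        remapped_quadrant=remapped,
        rotation_applied=rotation,
    )


# ---------------------------------------------------------------------------
# egg laying
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThreeWellPlate:
    """3-well oviposition plate (34 x 85 mm): three wells in a row.

    Well regions are discs; positions are cm in plate coordinates.
    """

    width: float = 3.4
    length: float = 8.5
    well_radius: float = 1.2

    @property
    def well_centers(self) -> tuple[tuple[float, float], ...]:
        x = self.width / 2.0
        ys = (self.length / 6.0, self.length / 2.0, 5.0 * self.length / 6.0)
        return tuple((x, y) for y in ys)


@dataclass(frozen=True)
class EggLayingConfig:
    """Ground-truth egg-laying law: expected total count and region weights.

    ``region_weights`` has one nonnegative entry per region (4 quadrants or
    3 wells); each egg falls in region i with probability w_i / sum(w) and
    uniform position within the region.
    """

    region_weights: tuple[float, ...]
    n_eggs_mean: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.region_weights, float)
        if (w < 0).any() or not (w > 0).any():
            raise ValueError("region_weights must be nonnegative with a positive sum")


def _uniform_in_quadrant(
    rng: np.random.Generator, arena: ArenaGeometry, quadrant: Quadrant, n: int
):
    """Uniform points in (mask intersect quadrant sector), by rejection."""
    from shapely import contains_xy

    poly = arena.mask
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(8 * (n - filled), 32)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        ok = contains_xy(poly, x, y) & (
            assign_quadrants(x, y, arena) == quadrant.index
        )
        k = min(int(ok.sum()), n - filled)
        out[filled : filled + k, 0] = x[ok][:k]
        out[filled : filled + k, 1] = y[ok][:k]
        filled += k
    return out


def simulate_eggs(cfg: EggLayingConfig, arena_or_wells):
    """Generate an egg-position table with known region weights.

    Total egg count is Poisson(``n_eggs_mean``); region assignment is
    multinomial on the weights; position is uniform within the region.
    Pass an :class:`ArenaGeometry` for 4-quadrant mode or a
    :class:`ThreeWellPlate` for 3-well mode.  Returns a DataFrame with
    columns egg_id, x_cm, y_cm, region.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    w = np.asarray(cfg.region_weights, float)
    if isinstance(arena_or_wells, ArenaGeometry):
        if len(w) != 4:
            raise ValueError("4-quadrant mode needs 4 region weights")
        regions = [q.value for q in (Quadrant.Q1, Quadrant.Q2, Quadrant.Q3, Quadrant.Q4)]
    elif isinstance(arena_or_wells, ThreeWellPlate):
        if len(w) != 3:
            raise ValueError("3-well mode needs 3 region weights")
        regions = ["well1", "well2", "well3"]
    else:
        raise TypeError("arena_or_wells must be ArenaGeometry or ThreeWellPlate")

    total = int(rng.poisson(cfg.n_eggs_mean))
    counts = rng.multinomial(total, w / w.sum())
    rows = []
    egg_id = 0
    for i, (region, k) in enumerate(zip(regions, counts)):
        if k == 0:
            continue
        if isinstance(arena_or_wells, ArenaGeometry):
            pts = _uniform_in_quadrant(
                rng, arena_or_wells, (Quadrant.Q1, Quadrant.Q2, Quadrant.Q3, Quadrant.Q4)[i], k
            )
        else:
            cx, cy = arena_or_wells.well_centers[i]
            r = arena_or_wells.well_radius * np.sqrt(rng.uniform(0, 1, k))
            th = rng.uniform(0, 2 * np.pi, k)
            pts = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
        for x, y in pts:
            rows.append((egg_id, float(x), float(y), region))
            egg_id += 1
    return pd.DataFrame(rows, columns=["egg_id", "x_cm", "y_cm", "region"])


# ---------------------------------------------------------------------------
# spike trains and EAG traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTrainConfig:
    """Inhomogeneous-Poisson spike train: baseline rate ``r0`` everywhere
    except a window of rate ``r1`` starting ``latency`` s after stimulus
    onset and lasting ``stim_duration`` s (1.0 s air pulse by default)."""

    baseline_rate: float = 10.0
    evoked_rate: float = 40.0
    stim_onset: float = 2.0
    stim_duration: float = 1.0
    latency: float = 0.5
    trial_duration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.evoked_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.stim_onset + self.stim_duration > self.trial_duration:
            raise ValueError("stimulus window must fit inside the trial")


def simulate_spike_train(cfg: SpikeTrainConfig, label: str = "odor") -> SpikeTrain:
    """Sample one spike train from the piecewise-constant rate profile."""
    rng = np.random.default_rng(cfg.seed)
    a = cfg.stim_onset + cfg.latency
    b = min(a + cfg.stim_duration, cfg.trial_duration)
    segments = [
        (0.0, a, cfg.baseline_rate),
        (a, b, cfg.evoked_rate),
        (b, cfg.trial_duration, cfg.baseline_rate),
    ]
    times = []
    for s0, s1, rate in segments:
        if s1 <= s0 or rate == 0:
            continue
        k = rng.poisson(rate * (s1 - s0))
        times.append(rng.uniform(s0, s1, k))
    spikes = np.sort(np.concatenate(times)) if times else np.empty(0)
    return SpikeTrain(
        spike_times=spikes,
        stim_onset=cfg.stim_onset,
        trial_duration=cfg.trial_duration,
        label=label,
    )


def simulate_eag_trace(
    amplitude: float,
    onset: float,
    noise_sd: float,
    fs: float,
    seed: int = 0,
    duration: float | None = None,
    rise_tau: float = 0.4,
):
    """Synthesize an EAG-like trace: zero baseline plus a smooth negative
    deflection whose sampled peak magnitude equals ``amplitude`` (mV)
    exactly when ``noise_sd`` is 0.

    Returns (t, v): sample times (s) and voltages (mV) at rate ``fs``.
    The deflection is an alpha function rescaled so its maximum over the
    actual sample grid equals ``amplitude``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if duration is None:
        duration = onset + 8.0 * rise_tau
    t = np.arange(int(round(duration * fs))) / fs
    rel = t - onset
    shape = np.where(rel > 0, (rel / rise_tau) * np.exp(1.0 - rel / rise_tau), 0.0)
    peak = shape.max()
    v = -amplitude * (shape / peak) if peak > 0 else np.zeros_like(t)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, v.shape)
    return t, v


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

def render_frames(
    tracks: TrackSet,
    arena: ArenaGeometry,
    fly_radius_px: int = 2,
    background: int = 230,
    foreground: int = 20,
) -> np.ndarray:
    """Render infrared-style frames: bright background, dark filled discs
    at each fly position.  Returns a uint8 array (n_frames, rows, cols);
    frame count spans 0 .. max track frame.  Positions whose centers fall
    outside the image raise."""
    from skimage.draw import disk

    if fly_radius_px < 1:
        raise ValueError("fly_radius_px must be >= 1")
    shape = arena.image_shape
    if not tracks.tracks:
        return np.full((0, *shape), background, dtype=np.uint8)
    n_frames = max(t.start_frame + len(t) for t in tracks.tracks)
    stack = np.full((n_frames, *shape), background, dtype=np.uint8)
    for tr in tracks.tracks:
        rows, cols = arena.cm_to_px(tr.xy[:, 0], tr.xy[:, 1])
        if (
            (rows < 0).any()
            or (cols < 0).any()
            or (rows >= shape[0]).any()
            or (cols >= shape[1]).any()
        ):
            raise ValueError(f"track {tr.id} has positions outside the image bounds")
        for k, f in enumerate(tr.frames):
            rr, cc = disk((rows[k], cols[k]), fly_radius_px, shape=shape)
            stack[f][rr, cc] = foreground
    return stack
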