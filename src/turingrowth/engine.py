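"""Growth-coupled Turing reaction-diffusion simulator.

The model is a two-morphogen activator-substrate system on a fixed periodic
grid.  Tissue growth is represented indirectly: each growth step dilutes the
morphogen concentrations (division by ``1 + g*dt``) and decays the effective
diffusion coefficient ``d`` (division by ``(1 + g*dt)**2``), which shortens
the pattern wavelength measured in grid units exactly as if the domain had
expanded.  The surface (area) of the virtual tissue is tracked as
``S(t) = 1/d(t)``: one growth step multiplies the surface by ``(1+g*dt)**2``
(each axis stretches by ``1+g*dt``).

Update rule (synchronous, explicit Euler, nine-point periodic Laplacian)::

    a' = clamp( a/(1+g*dt) + (16 - a*b/(1+g*dt)^2 + d*r*s*lap(a)) * dt )
    b' = clamp( b/(1+g*dt) + (a*b/(1+g*dt)^2 - b/(1+g*dt) - 12 + d*s*lap(b)) * dt )

with a clamped to [0, 4.4] and b to [3.5, 100].  The homogeneous fixed point
is (a, b) = (4, 4).  Growth is off (g_now = 0) until iteration ``t_start``
and switches off again once the surface reaches ``max_surface``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "DT",
    "MIN_A",
    "MAX_A",
    "MIN_B",
    "MAX_B",
    "FIXED_POINT",
    "PRESETS",
    "ReactionParams",
    "GrowthSchedule",
    "SimulationConfig",
    "SimulationHistory",
    "SimulationDivergedError",
    "laplacian9",
    "reaction_step",
    "make_initial_condition",
    "run_simulation",
    "preset_config",
]

# Fixed parameters shared by all published simulations.
DT = 0.002
MIN_A = 0.0
MAX_A = 4.4
MIN_B = 3.5
MAX_B = 100.0
#: Homogeneous steady state of the reaction terms (16 - a*b = 0, a*b - b - 12 = 0).
FIXED_POINT = (4.0, 4.0)

_STENCIL = np.array([[1.0, 4.0, 1.0], [4.0, -20.0, 4.0], [1.0, 4.0, 1.0]]) / 6.0

InitialConditionKind = Literal["random_noise", "middle_stripe", "periodic_stripes"]


class SimulationDivergedError(RuntimeError):
    """Raised when a field becomes non-finite during a simulation."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"simulation diverged (non-finite field) at iteration {iteration}")


@dataclass(frozen=True)
class ReactionParams:
    """Reaction/diffusion parameters.

    ``s`` and ``r`` are the scale and ratio parameters; the substrate ``a``
    diffuses with coefficient ``d*r*s`` and the activator ``b`` with ``d*s``.
    ``d`` is the initial value of the time-varying diffusion multiplier
    (decayed by growth); any other constant would be absorbed into ``s``.
    """

    s: float
    r: float
    d: float = 1.0
    dt: float = DT
    min_a: float = MIN_A
    max_a: float = MAX_A
    min_b: float = MIN_B
    max_b: float = MAX_B

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.s <= 0 or self.r <= 0 or self.d <= 0:
            raise ValueError("s, r and d must be positive")
        if not (self.min_a < self.max_a and self.min_b < self.max_b):
            raise ValueError("clamp bounds must satisfy min < max")


@dataclass(frozen=True)
class GrowthSchedule:
    """When and how fast the tissue surface grows.

    ``g`` is the growth rate of the surface per unit time; growth is inactive
    before iteration ``t_start`` and stops once the surface has reached
    ``max_surface`` times its initial value.  ``anisotropy`` optionally gives
    per-axis rates ``(g_y, g_x)`` whose combination replaces the isotropic
    rate (the isotropic case corresponds to ``(g, g)`` with each axis
    stretched by ``1 + g*dt`` per step).  ``couple_diffusion`` toggles the
    cumulative decay of the diffusion multiplier; with it off only dilution
    acts and the wavelength in grid units is unchanged by growth.
    """

    g: float = 0.0
    t_start: int = 10_000
    max_surface: float = 4.0
    anisotropy: tuple[float, float] | None = None
    couple_diffusion: bool = True

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("growth rate must be non-negative")
        if self.t_start < 0:
            raise ValueError("t_start must be non-negative")
        if self.max_surface < 1:
            raise ValueError("max_surface must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    reaction: ReactionParams
    growth: GrowthSchedule
    shape: tuple[int, int] = (200, 200)
    initial_condition: InitialConditionKind = "random_noise"
    n_iter: int = 75_000
    snapshot_interval: int = 250
    seed: int = 0
    noise_amplitude: float = 0.5
    n_stripes: int = 5
    stripe_width: int | None = None

    def __post_init__(self):
        if self.n_iter < self.growth.t_start and self.growth.g > 0:
            raise ValueError("n_iter must cover the growth start")
        if self.snapshot_interval < 1:
            raise ValueError("snapshot_interval must be >= 1")
        if min(self.shape) < 3:
            raise ValueError("grid must be at least 3x3")


@dataclass
class SimulationHistory:
    """Snapshots of a simulation, taken every ``snapshot_interval`` steps.

    Extra snapshots are recorded at the exact start and end of the growth
    phase; ``iterations`` is therefore strictly increasing but not perfectly
    regular.  ``surface`` is the tissue surface S(t) at each snapshot.
    """

    config: SimulationConfig
    iterations: list[int] = field(default_factory=list)
    surface: list[float] = field(default_factory=list)
    a_snapshots: list[np.ndarray] = field(default_factory=list)
    b_snapshots: list[np.ndarray] = field(default_factory=list)
    growth_start_iteration: int | None = None
    growth_end_iteration: int | None = None

    def __len__(self) -> int:
        return len(self.iterations)

    def _append(self, t: int, s: float, a: np.ndarray, b: np.ndarray) -> None:
        if self.iterations and t <= self.iterations[-1]:
            return
        self.iterations.append(t)
        self.surface.append(s)
        self.a_snapshots.append(a.astype(np.float32))
        self.b_snapshots.append(b.astype(np.float32))

    def index_at(self, iteration: int) -> int:
        """Index of the last snapshot taken at or before ``iteration``."""
        idx = int(np.searchsorted(self.iterations, iteration, side="right")) - 1
        if idx < 0:
            raise ValueError(f"no snapshot at or before iteration {iteration}")
        return idx


def laplacian9(values: np.ndarray) -> np.ndarray:
    """Discrete Laplacian with the nine-point (Moore neighbourhood) stencil
    [[1,4,1],[4,-20,4],[1,4,1]]/6 and periodic wrap on both axes."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or min(values.shape) < 3:
        raise ValueError("field must be 2D and at least 3x3")
    # difference form (neighbour - centre): exactly zero on constant fields
    out = np.zeros_like(values)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            w = _STENCIL[di + 1, dj + 1]
            out += w * (np.roll(np.roll(values, -di, axis=0), -dj, axis=1) - values)
    return out


def reaction_step(
    a: np.ndarray,
    b: np.ndarray,
    params: ReactionParams,
    g_now: float = 0.0,
    d: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One synchronous update of the two fields; returns (a', b', d').

    ``g_now`` is the instantaneous growth rate (zero outside the growth
    phase); ``d`` the current diffusion multiplier (defaults to ``params.d``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have the same shape")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise FloatingPointError("non-finite input field")
    if d is None:
        d = params.d
    dt = params.dt
    dil = 1.0 + g_now * dt
    dil2 = dil * dil
    lap_a = laplacian9(a)
    lap_b = laplacian9(b)
    ab = a * b / dil2
    a2 = a / dil + (16.0 - ab + d * params.r * params.s * lap_a) * dt
    b2 = b / dil + (ab - b / dil - 12.0 + d * params.s * lap_b) * dt
    np.clip(a2, params.min_a, params.max_a, out=a2)
    np.clip(b2, params.min_b, params.max_b, out=b2)
    d2 = d / dil2 if g_now > 0 else d
    return a2, b2, d2


def make_initial_condition(
    kind: InitialConditionKind,
    shape: tuple[int, int],
    seed: int,
    noise_amplitude: float = 0.5,
    n_stripes: int = 5,
    stripe_width: int | None = None,
    params: ReactionParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (a, b) fields for one of the three named initial conditions.

    ``random_noise`` perturbs the homogeneous fixed point uniformly by
    ±``noise_amplitude``.  The stripe conditions place activator stripes
    (a at its ceiling) on the fixed-point background, plus a small seeded
    perturbation (±0.05) so that the along-stripe symmetry can break.
    """
    if min(shape) < 3:
        raise ValueError("grid must be at least 3x3")
    max_a = params.max_a if params is not None else MAX_A
    rng = np.random.default_rng(seed)
    a0, b0 = FIXED_POINT
    min_a = params.min_a if params is not None else MIN_A
    min_b = params.min_b if params is not None else MIN_B
    max_b = params.max_b if params is not None else MAX_B
    if kind == "random_noise":
        a = a0 + rng.uniform(-noise_amplitude, noise_amplitude, size=shape)
        b = b0 + rng.uniform(-noise_amplitude, noise_amplitude, size=shape)
        np.clip(a, min_a, max_a, out=a)
        np.clip(b, min_b, max_b, out=b)
        return a, b
    if kind not in ("middle_stripe", "periodic_stripes"):
        raise ValueError(f"unknown initial condition kind: {kind!r}")
    h, w = shape
    width = stripe_width if stripe_width is not None else max(3, round(0.05 * w))
    a = np.full(shape, a0)
    b = np.full(shape, float(b0))
    centers = [w / 2] if kind == "middle_stripe" else [(k + 0.5) * w / n_stripes for k in range(n_stripes)]
    cols = np.arange(w)
    for c in centers:
        dist = np.minimum(np.abs(cols - c), w - np.abs(cols - c))  # periodic distance
        a[:, dist <= width / 2] = max_a
    a += rng.uniform(-0.05, 0.05, size=shape)
    b += rng.uniform(-0.05, 0.05, size=shape)
    np.clip(a, min_a, max_a, out=a)
    np.clip(b, min_b, max_b, out=b)
    return a, b


def growth_duration(g: float, max_surface: float, dt: float = DT) -> int:
    """Number of growth steps needed for the surface to reach max_surface
    (each step multiplies the surface by (1+g*dt)**2)."""
    if g <= 0 or max_surface <= 1:
        return 0
    return math.ceil(math.log(max_surface) / (2.0 * math.log1p(g * dt)))


def _step_numpy(a, b, params, g_now, d):
    return reaction_step(a, b, params, g_now, d)


def run_simulation(config: SimulationConfig, use_numba: bool = True) -> SimulationHistory:
    """Run the full schedule and return the snapshot history.

    Growth is inactive for ``t < t_start``, active at rate ``g`` until the
    surface reaches ``max_surface``, then inactive again while the system
    relaxes toward its new equilibrium.  Fully reproducible from the config
    seed.  Raises :class:`SimulationDivergedError` if a field goes
    non-finite.
    """
    p = config.reaction
    gr = config.growth
    if gr.anisotropy is not None:
        return _run_anisotropic(config)

    a, b = make_initial_condition(
        config.initial_condition,
        config.shape,
        config.seed,
        noise_amplitude=config.noise_amplitude,
        n_stripes=config.n_stripes,
        stripe_width=config.stripe_width,
        params=p,
    )
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)

    n_growth = growth_duration(gr.g, gr.max_surface, p.dt) if gr.g > 0 else 0
    growth_start = gr.t_start if n_growth else None
    growth_end = gr.t_start + n_growth if n_growth else None

    hist = SimulationHistory(config=config)
    hist.growth_start_iteration = growth_start
    hist.growth_end_iteration = growth_end

    d = p.d
    surface = 1.0
    hist._append(0, surface, a, b)

    # Chunk boundaries: snapshot cadence plus the exact growth start/end.
    marks = set(range(config.snapshot_interval, config.n_iter + 1, config.snapshot_interval))
    marks.add(config.n_iter)
    if growth_start is not None:
        marks.add(growth_start)
        marks.add(min(growth_end, config.n_iter))
    boundaries = sorted(m for m in marks if 0 < m <= config.n_iter)

    if use_numba:
        from ._kernels import run_chunk
    else:
        run_chunk = None

    t = 0
    for t_next in boundaries:
        n_steps = t_next - t
        # growth rate is constant within a chunk by construction of boundaries
        in_growth = growth_start is not None and growth_start <= t < growth_end
        g_now = gr.g if in_growth else 0.0
        if run_chunk is not None:
            a, b, d, surface = run_chunk(
                a, b, n_steps, p.s, p.r, d, surface, g_now, p.dt,
                gr.couple_diffusion, p.min_a, p.max_a, p.min_b, p.max_b,
            )
        else:
            for _ in range(n_steps):
                a, b, d_new = reaction_step(a, b, p, g_now, d)
                if g_now > 0:
                    surface *= (1.0 + g_now * p.dt) ** 2
                    d = d_new if gr.couple_diffusion else d
        t = t_next
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise SimulationDivergedError(t)
        hist._append(t, surface, a, b)
    return hist


def _run_anisotropic(config: SimulationConfig) -> SimulationHistory:
    """Anisotropic growth: per-axis rates (g_y, g_x), per-axis diffusion decay
    through an axis-split Laplacian.  Pure-numpy path (small scenarios only)."""
    p = config.reaction
    gr = config.growth
    g_y, g_x = gr.anisotropy
    a, b = make_initial_condition(
        config.initial_condition, config.shape, config.seed,
        noise_amplitude=config.noise_amplitude, n_stripes=config.n_stripes,
        stripe_width=config.stripe_width, params=p,
    )
    hist = SimulationHistory(config=config)
    hist.growth_start_iteration = gr.t_start
    d_y = d_x = p.d
    surface = 1.0
    dt = p.dt
    hist._append(0, surface, a, b)
    for t in range(1, config.n_iter + 1):
        growing = t - 1 >= gr.t_start and surface < gr.max_surface
        gy = g_y if growing else 0.0
        gx = g_x if growing else 0.0
        step = (1.0 + gy * dt) * (1.0 + gx * dt)
        dil = math.sqrt(step)  # per-step dilution: geometric mean of axis factors
        lyy_a = np.roll(a, 1, axis=0) - 2 * a + np.roll(a, -1, axis=0)
        lxx_a = np.roll(a, 1, axis=1) - 2 * a + np.roll(a, -1, axis=1)
        lyy_b = np.roll(b, 1, axis=0) - 2 * b + np.roll(b, -1, axis=0)
        lxx_b = np.roll(b, 1, axis=1) - 2 * b + np.roll(b, -1, axis=1)
        diff_a = p.r * p.s * (d_y * lyy_a + d_x * lxx_a)
        diff_b = p.s * (d_y * lyy_b + d_x * lxx_b)
        ab = a * b / (dil * dil)
        a, b = (
            np.clip(a / dil + (16.0 - ab + diff_a) * dt, p.min_a, p.max_a),
            np.clip(b / dil + (ab - b / dil - 12.0 + diff_b) * dt, p.min_b, p.max_b),
        )
        if growing:
            surface *= step
            if gr.couple_diffusion:
                d_y /= (1.0 + gy * dt) ** 2
                d_x /= (1.0 + gx * dt) ** 2
            if surface >= gr.max_surface and hist.growth_end_iteration is None:
                hist.growth_end_iteration = t
        if t % config.snapshot_interval == 0 or t == config.n_iter:
            if not (np.isfinite(a).all() and np.isfinite(b).all()):
                raise SimulationDivergedError(t)
            hist._append(t, surface, a, b)
    return hist


#: Published simulation presets (initial condition, s, r, g, growth start).
PRESETS: dict[str, dict] = {
    "leopard": dict(s=6.0, r=30.0, g=0.05, initial_condition="random_noise", t_start=10_000),
    "emu": dict(s=10.0, r=6.0, g=0.05, initial_condition="middle_stripe", t_start=10_000),
    "pomacanthus": dict(s=10.0, r=6.0, g=0.05, initial_condition="middle_stripe", t_start=20_000),
    "ictidomys": dict(s=6.0, r=30.0, g=0.01, initial_condition="periodic_stripes", t_start=1_000),
    "tetraodon": dict(s=10.0, r=8.0, g=0.075, initial_condition="random_noise", t_start=10_000),
}


def preset_config(
    name: str,
    shape: tuple[int, int] = (200, 200),
    n_iter: int = 75_000,
    seed: int = 0,
    max_surface: float = 4.0,
    snapshot_interval: int = 250,
    **overrides,
) -> SimulationConfig:
    """Build a :class:`SimulationConfig` for one of the named presets."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    reaction = ReactionParams(s=spec["s"], r=spec["r"])
    growth = GrowthSchedule(g=spec["g"], t_start=spec["t_start"], max_surface=max_surface)
    cfg = SimulationConfig(
        reaction=reaction,
        growth=growth,
        shape=shape,
        initial_condition=spec["initial_condition"],
        n_iter=n_iter,
        snapshot_interval=snapshot_interval,
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
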