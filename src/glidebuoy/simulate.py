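"""Synthetic tag data with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
population of tagged individuals with per-individual tissue density and
drag term, per-dive diving gas volume around a population mean, and one
global tissue compressibility.  Two products are available:

* ``simulate_glide_table`` draws 5-s glide observations directly from the
  hydrodynamic model plus Gaussian measurement noise — the object the
  Bayesian fit consumes.
* ``simulate_tag_record`` builds a full depth/acceleration record of
  stroke-and-glide dives (stroking bouts with an oscillatory dorso-ventral
  signature, glide bouts integrated from the glide dynamics), so the whole
  extraction pipeline can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .hydro import HydroParams, glide_acceleration, simulate_glide
from .tagdata import SEGMENT_COLUMNS, TagRecord

__all__ = [
    "TruthConfig",
    "PopulationTruth",
    "GlideTableDesign",
    "DivePlan",
    "draw_truth",
    "simulate_glide_table",
    "simulate_tag_record",
]


@dataclass(frozen=True)
class TruthConfig:
    """Generating hyperparameters of the synthetic population.

    Defaults emulate the fitted population of deep-diving whales: mean
    tissue density 1031.5 kg m^-3 with ~1.5 kg m^-3 between-individual
    spread (individuals spanning roughly 1028-1034), drag terms around
    12.6e-6 m^2 kg^-1, dive gas volumes around 27.4 ml kg^-1, and a
    global tissue compressibility of 0.38e-9 Pa^-1.
    """

    n_individuals: int = 12
    dives_per_individual: int = 10
    density_mean: float = 1031.5
    density_sd: float = 1.5
    density_bounds: Tuple[float, float] = (800.0, 1200.0)
    drag_mean: float = 12.6e-6
    drag_sd: float = 2.0e-6
    drag_bounds: Tuple[float, float] = (5.0e-6, 20.0e-6)
    gas_mean: float = 27.4
    gas_dive_sd: float = 15.0
    gas_bounds: Tuple[float, float] = (0.0, 200.0)
    r: float = 0.38e-9

    def __post_init__(self) -> None:
        if not (self.density_bounds[0] <= self.density_mean <= self.density_bounds[1]):
            raise ValueError("density_mean outside its bounds")
        if not (self.drag_bounds[0] <= self.drag_mean <= self.drag_bounds[1]):
            raise ValueError("drag_mean outside its bounds")
        if not (self.gas_bounds[0] <= self.gas_mean <= self.gas_bounds[1]):
            raise ValueError("gas_mean outside its bounds")
        if min(self.density_sd, self.drag_sd, self.gas_dive_sd) < 0:
            raise ValueError("spreads must be non-negative")


@dataclass
class PopulationTruth:
    """Known generating parameters for a synthetic population."""

    individual_ids: List[str]
    rho_tissue: np.ndarray  # per individual
    drag_term: np.ndarray  # per individual
    dive_individual: np.ndarray  # dive -> individual index
    dive_ids: np.ndarray  # dive id within individual
    vair_per_mass: np.ndarray  # per dive
    r: float
    config: TruthConfig
    seed: int

    def params_for_dive(self, j: int) -> HydroParams:
        i = int(self.dive_individual[j])
        return HydroParams(
            drag_term=float(self.drag_term[i]),
            rho_tissue=float(self.rho_tissue[i]),
            vair_per_mass=float(self.vair_per_mass[j]),
            r=self.r,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in range(len(self.vair_per_mass)):
            i = int(self.dive_individual[j])
            rows.append({
                "individual_id": self.individual_ids[i],
                "dive_id": int(self.dive_ids[j]),
                "rho_tissue": float(self.rho_tissue[i]),
                "drag_term": float(self.drag_term[i]),
                "vair_per_mass": float(self.vair_per_mass[j]),
                "r": self.r,
            })
        return pd.DataFrame(rows)


def _trunc_normal(rng, mean, sd, bounds, size):
    """Truncated-normal draws by rejection (exact; spreads are mild)."""
    if sd == 0:
        return np.full(size, float(mean))
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        cand = rng.normal(mean, sd, size=todo.size)
        ok = (cand >= bounds[0]) & (cand <= bounds[1])
        out[todo[ok]] = cand[ok]
        todo = todo[~ok]
    return out


def draw_truth(config: TruthConfig = TruthConfig(), seed: int = 0) -> PopulationTruth:
    """Draw per-individual and per-dive generating values (reproducible)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(101,)))
    n, nd = config.n_individuals, config.dives_per_individual
    rho = _trunc_normal(rng, config.density_mean, config.density_sd, config.density_bounds, n)
    drag = _trunc_normal(rng, config.drag_mean, config.drag_sd, config.drag_bounds, n)
    gas = _trunc_normal(rng, config.gas_mean, config.gas_dive_sd, config.gas_bounds, n * nd)
    return PopulationTruth(
        individual_ids=[f"ind{i:02d}" for i in range(n)],
        rho_tissue=rho,
        drag_term=drag,
        dive_individual=np.repeat(np.arange(n), nd),
        dive_ids=np.tile(np.arange(nd), n),
        vair_per_mass=gas,
        r=config.r,
        config=config,
        seed=int(seed),
    )


@dataclass(frozen=True)
class GlideTableDesign:
    """Sampling design of a synthetic glide-segment table.

    Depths are log-uniform over ``depth_range`` so that the shallow
    depths that carry the gas-volume information are well represented;
    pitches are uniform in magnitude over ``pitch_deg_range`` (descent
    negative, ascent positive); the per-segment acceleration noise s.d.
    is uniform over ``sigma_a_range``, emulating the observed spread of
    residual RMS values.
    """

    glides_per_individual: int = 300
    depth_range: Tuple[float, float] = (20.0, 800.0)
    pitch_deg_range: Tuple[float, float] = (30.0, 80.0)
    speed_range: Tuple[float, float] = (0.8, 2.5)
    sigma_a_range: Tuple[float, float] = (0.005, 0.05)
    ascent_fraction: float = 0.5


def simulate_glide_table(
    truth: PopulationTruth,
    design: GlideTableDesign = GlideTableDesign(),
    density_profile=None,
    seed: int = 0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Draw a glide-segment table directly from the glide dynamics.

    Observed acceleration is the model acceleration at the drawn
    (v, p, d) plus Normal(0, sigma_a) noise.  Pitch magnitudes respect
    the >= 30 degree segment filter by construction.  ``density_profile``
    defaults to a constant 1027 kg m^-3 ocean when omitted.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(202,)))
    if density_profile is None:
        density_profile = lambda d: np.full_like(np.asarray(d, dtype=float), 1027.0)
    if design.glides_per_individual < 1:
        raise ValueError("design yields zero segments")
    n_dives_total = len(truth.vair_per_mass)
    rows = []
    for j in range(n_dives_total):
        i = int(truth.dive_individual[j])
        params = truth.params_for_dive(j)
        nd = truth.config.dives_per_individual
        n_glides = design.glides_per_individual // nd + (
            1 if j % nd < design.glides_per_individual % nd else 0
        )
        for _ in range(n_glides):
            lo, hi = design.depth_range
            d = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            ascent = rng.uniform() < design.ascent_fraction
            p_mag = np.deg2rad(rng.uniform(*design.pitch_deg_range))
            p = p_mag if ascent else -p_mag
            v = float(rng.uniform(*design.speed_range))
            sigma = float(rng.uniform(*design.sigma_a_range))
            rho_sw = float(np.asarray(density_profile(d)))
            a_true = glide_acceleration(params, v, p, d, rho_sw, constants)
            rows.append({
                "individual_id": truth.individual_ids[i],
                "dive_id": int(truth.dive_ids[j]),
                "phase": "ascent" if ascent else "descent",
                "v": v,
                "a": float(a_true + rng.normal(0.0, sigma)),
                "sigma_a": sigma,
                "d": d,
                "p": float(p),
                "rho_sw": rho_sw,
                "roll_circvar": 0.0,
            })
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


@dataclass(frozen=True)
class DivePlan:
    """Structure of a simulated stroke-and-glide dive record."""

    n_dives: int = 4
    max_depth_mean: float = 400.0
    max_depth_sd: float = 40.0
    descent_pitch_deg: float = -60.0
    ascent_pitch_deg: float = 60.0
    bottom_duration: float = 60.0
    surface_duration: float = 120.0
    stroke_bout_range: Tuple[float, float] = (6.0, 14.0)
    glide_bout_range: Tuple[float, float] = (8.0, 25.0)
    cruise_speed: float = 1.5
    thrust_tau: float = 5.0
    stroke_freq: float = 0.4
    stroke_amp: float = 0.8
    accel_noise_sd: float = 0.02
    sample_rate: float = 5.0
    # a glide bout is abandoned once speed decays below this; ~2/3 of the
    # cruise speed, so gliding concentrates in the buoyancy-aided direction
    min_glide_speed: float = 1.0

    def __post_init__(self) -> None:
        if self.max_depth_mean > 1500.0:
            raise ValueError("dive depths limited to 1500 m")
        for p in (self.descent_pitch_deg, self.ascent_pitch_deg):
            if abs(p) > 90:
                raise ValueError("pitch outside +/-90 deg")


class _RecordBuilder:
    def __init__(self, fs: float, rng):
        self.fs = fs
        self.rng = rng
        self.depth: List[float] = []
        self.ax: List[float] = []
        self.ay: List[float] = []
        self.az: List[float] = []
        self.glide_mask: List[bool] = []

    def add(self, depth, pitch, dvdt, stroking: bool, plan: DivePlan):
        t0 = len(self.depth) / self.fs
        n = len(depth)
        t = t0 + np.arange(n) / self.fs
        g = 9.8
        osc = (
            plan.stroke_amp * np.sin(2 * np.pi * plan.stroke_freq * t)
            if stroking
            else np.zeros(n)
        )
        noise = self.rng.normal(0.0, plan.accel_noise_sd, size=(n, 3))
        self.depth.extend(np.asarray(depth, dtype=float))
        self.ax.extend(g * np.sin(pitch) + dvdt + noise[:, 0])
        self.ay.extend(noise[:, 1])
        self.az.extend(g * np.cos(pitch) + osc + noise[:, 2])
        self.glide_mask.extend([not stroking] * n)


def _stroke_bout(builder, plan, depth, speed, pitch, duration):
    fs = builder.fs
    n = max(int(round(duration * fs)), 1)
    dt = 1.0 / fs
    depths = np.empty(n)
    dvdt = np.empty(n)
    sinp = np.sin(pitch)
    for k in range(n):
        acc = (plan.cruise_speed - speed) / plan.thrust_tau
        dvdt[k] = acc
        speed = speed + acc * dt
        depth = max(depth - speed * sinp * dt, 0.0)
        depths[k] = depth
    builder.add(depths, np.full(n, pitch), dvdt, True, plan)
    return depth, speed


def _glide_bout(builder, plan, params, density_profile, depth, speed, pitch, duration, constants):
    # integrate finer than the record step (RK4 needs dt <= 0.1 s), then
    # subsample onto record samples
    sub = max(int(np.ceil(10.0 / builder.fs)), 1)
    dt = 1.0 / (builder.fs * sub)
    traj = simulate_glide(
        params, speed, pitch, depth, duration, dt=dt,
        density_profile=density_profile, constants=constants,
    )
    v = traj.speed[::sub]
    d = traj.depth[::sub]
    stop = len(v)
    vmin_idx = np.where(v < plan.min_glide_speed)[0]
    if vmin_idx.size:
        stop = max(int(vmin_idx[0]), 2)
    v, d = v[:stop], d[:stop]
    dvdt = np.gradient(v) * builder.fs
    builder.add(d, np.full(len(d), pitch), dvdt, False, plan)
    return float(d[-1]), float(v[-1])


def simulate_tag_record(
    truth: PopulationTruth,
    plan: DivePlan = DivePlan(),
    density_profile=None,
    seed: int = 0,
    individual: int = 0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Simulate one individual's full tag record of stroke-and-glide dives.

    Returns ``(record, glide_intervals)`` where ``glide_intervals`` is the
    list of planted glide intervals (seconds) for round-trip checks.
    Descent and ascent alternate stroking bouts (thrust relaxing speed
    toward the cruise speed, with a stroking oscillation on the
    dorso-ventral axis) and glide bouts integrated from the glide
    dynamics; a glide bout ends early once speed decays below
    ``plan.min_glide_speed``.  Roll is held near zero so the stability
    filter passes by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(303, individual)))
    if density_profile is None:
        density_profile = lambda d: 1027.0 + 0.0 * np.asarray(d, dtype=float)
    fs = plan.sample_rate
    builder = _RecordBuilder(fs, rng)
    dive_rows = np.where(truth.dive_individual == individual)[0]
    if dive_rows.size == 0:
        raise ValueError(f"truth has no dives for individual {individual}")

    builder.add(np.zeros(int(plan.surface_duration * fs)), np.zeros(1), 0.0, True, plan)
    for k in range(plan.n_dives):
        j = int(dive_rows[k % dive_rows.size])
        params = truth.params_for_dive(j)
        target = max(float(rng.normal(plan.max_depth_mean, plan.max_depth_sd)), 100.0)
        depth, speed = 0.0, plan.cruise_speed
        pitch = np.deg2rad(plan.descent_pitch_deg)
        # descent: stroke first, then alternate
        depth, speed = _stroke_bout(builder, plan, depth, speed, pitch,
                                    rng.uniform(*plan.stroke_bout_range))
        while depth < target:
            depth, speed = _glide_bout(
                builder, plan, params, density_profile, depth, speed, pitch,
                rng.uniform(*plan.glide_bout_range), constants,
            )
            if depth >= target:
                break
            depth, speed = _stroke_bout(builder, plan, depth, speed, pitch,
                                        rng.uniform(*plan.stroke_bout_range))
        # bottom: level stroking
        depth, speed = _stroke_bout(builder, plan, depth, speed, 0.0, plan.bottom_duration)
        # ascent
        pitch = np.deg2rad(plan.ascent_pitch_deg)
        depth, speed = _stroke_bout(builder, plan, depth, speed, pitch,
                                    rng.uniform(*plan.stroke_bout_range))
        while depth > 0.0:
            depth, speed = _glide_bout(
                builder, plan, params, density_profile, depth, speed, pitch,
                rng.uniform(*plan.glide_bout_range), constants,
            )
            if depth <= 0.0:
                break
            depth, speed = _stroke_bout(builder, plan, depth, speed, pitch,
                                        rng.uniform(*plan.stroke_bout_range))
        builder.add(np.zeros(int(plan.surface_duration * fs)), np.zeros(1), 0.0, True, plan)

    n = len(builder.depth)
    time = np.arange(n) / fs
    accel = np.column_stack([builder.ax, builder.ay, builder.az])
    record = TagRecord(
        individual_id=truth.individual_ids[individual],
        sample_rate=fs,
        time=time,
        depth=np.asarray(builder.depth),
        accel=accel,
        location_tag="synthetic",
    )
    mask = np.asarray(builder.glide_mask)
    edges = np.diff(mask.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(n)
    intervals = [(s / fs, e / fs) for s, e in zip(starts, ends)]
    return record, intervals
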