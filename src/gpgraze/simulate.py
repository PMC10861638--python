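"""Genotype-structured synthetic herds: correlated random walks over terrain.

The generator exists so the full analysis pipeline (QC -> behaviour metrics ->
balanced cohort -> discriminant model -> association statistics) can be
exercised with known ground truth.  Each cow follows a correlated random walk:
its heading persists from step to step (wrapped-normal turning noise whose
concentration controls tortuosity), is pulled uphill and toward a preferred
relative elevation through the local terrain gradient, and its step lengths
are lognormal with a per-day multiplicative factor that creates genuine
day-to-day variability (the CV-type behaviours).  GPS observation noise and
independent fix dropout emulate collar data.

Randomness policy: a master seed; per-cow streams are spawned from
``SeedSequence(master_seed, farm_index, cow_index)`` so adding cows or farms
never perturbs existing trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .terrain import TerrainModel, generate_terrain

__all__ = [
    "GenotypeProfile",
    "SimulationConfig",
    "GENOTYPES",
    "VARIANTS",
    "default_profiles",
    "identical_profiles",
    "simulate_trajectory",
    "simulate_herd",
    "farm_terrain",
]

GENOTYPES = ("AB", "AC", "BB", "BC", "CC")
VARIANTS = ("A", "B", "C")

FIX_TABLE_COLUMNS = [
    "cow_id",
    "farm_id",
    "genotype",
    "timestamp_iso8601",
    "easting_m",
    "northing_m",
]


@dataclass(frozen=True)
class GenotypeProfile:
    """Movement phenotype attached to a genotype label.

    Parameters
    ----------
    step_length_mean : float
        Mean displacement per fix interval, metres.
    step_length_sigma : float
        Log-scale dispersion of the lognormal step-length distribution.
    turn_concentration : float
        Concentration of the wrapped-normal turning noise; higher values give
        straighter paths (sd of a turn is ``1/sqrt(concentration)`` radians).
    uphill_bias : float
        Drift weight along the local upslope direction (unitless).
    elevation_preference : float
        Preferred elevation as a fraction of the terrain relief (0 = valley
        floor, 1 = summit).
    elevation_attraction : float
        Drift weight toward the preferred elevation band (unitless).
    day_variability : float
        Log-scale sd of the per-day lognormal multiplier applied to step
        length and uphill bias; drives between-day CV metrics.
    """

    genotype: str
    step_length_mean: float = 15.0
    step_length_sigma: float = 0.6
    turn_concentration: float = 1.0
    uphill_bias: float = 0.0
    elevation_preference: float = 0.5
    elevation_attraction: float = 0.0
    day_variability: float = 0.3

    def __post_init__(self):
        if self.step_length_mean <= 0:
            raise ValueError("step length must be positive")
        if self.turn_concentration < 0:
            raise ValueError("turning-angle concentration must be >= 0")


def default_profiles() -> list[GenotypeProfile]:
    """The five stock genotype movement profiles.

    Deliberately separated on several generative axes (step length, turning
    concentration, uphill/elevation attraction, day-to-day variability) so the
    behavioural phenotypes the pipeline measures - daily distance, tortuosity,
    elevation gain and range, and their CVs - differ between genotypes by
    construction.
    """
    return [
        GenotypeProfile("AB", step_length_mean=12.0, step_length_sigma=0.5,
                        turn_concentration=1.0, uphill_bias=0.15,
                        elevation_preference=0.30, elevation_attraction=0.6,
                        day_variability=0.15),
        GenotypeProfile("AC", step_length_mean=16.0, step_length_sigma=0.5,
                        turn_concentration=2.0, uphill_bias=0.40,
                        elevation_preference=0.75, elevation_attraction=0.8,
                        day_variability=0.25),
        GenotypeProfile("BB", step_length_mean=10.0, step_length_sigma=0.7,
                        turn_concentration=0.4, uphill_bias=0.00,
                        elevation_preference=0.15, elevation_attraction=0.8,
                        day_variability=0.35),
        GenotypeProfile("BC", step_length_mean=14.0, step_length_sigma=0.6,
                        turn_concentration=0.25, uphill_bias=0.30,
                        elevation_preference=0.55, elevation_attraction=0.3,
                        day_variability=0.50),
        GenotypeProfile("CC", step_length_mean=20.0, step_length_sigma=0.4,
                        turn_concentration=3.0, uphill_bias=0.10,
                        elevation_preference=0.50, elevation_attraction=0.1,
                        day_variability=0.70),
    ]


def identical_profiles() -> list[GenotypeProfile]:
    """Five genotype labels sharing one movement phenotype (null scenario)."""
    base = GenotypeProfile("AB", step_length_mean=14.0, step_length_sigma=0.55,
                           turn_concentration=1.0, uphill_bias=0.2,
                           elevation_preference=0.5, elevation_attraction=0.5,
                           day_variability=0.3)
    return [GenotypeProfile(g, **{k: v for k, v in asdict(base).items() if k != "genotype"})
            for g in GENOTYPES]


@dataclass(frozen=True)
class SimulationConfig:
    """Herd-level simulation settings (the study-design constants)."""

    n_farms: int = 4
    paddock_area_ha: float = 34.5
    fix_interval_s: int = 300
    days: int = 15
    cows_per_genotype_per_farm: int = 7
    gps_noise_sd: float = 5.0
    dropout_probability: float = 0.10
    cell_size: float = 16.0
    relief_amplitude: float = 300.0
    base_elevation: float = 400.0
    individual_variation: float = 0.12
    seed: int = 0
    start_date: str = "2020-06-01"

    def __post_init__(self):
        if 86400 % self.fix_interval_s != 0:
            raise ValueError("fix interval must divide 86400 seconds")
        if self.days < 1:
            raise ValueError("at least one day per deployment")
        if not (0.0 <= self.dropout_probability < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")

    @property
    def fixes_per_day(self) -> int:
        return 86400 // self.fix_interval_s

    @property
    def paddock_side_m(self) -> float:
        return float(np.sqrt(self.paddock_area_ha * 1e4))


def _cow_stream(config_seed: int, farm_index: int, cow_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config_seed, farm_index, cow_index))
    )


def _individualize(
    profile: GenotypeProfile, rng: np.random.Generator, rel_sd: float
) -> GenotypeProfile:
    """Per-cow phenotype: multiplicative lognormal jitter (unit mean) on the
    genotype profile, so cows of a genotype vary realistically around it."""
    if rel_sd <= 0:
        return profile
    def jig(value):
        return value * np.exp(rng.standard_normal() * rel_sd - 0.5 * rel_sd**2)
    return GenotypeProfile(
        profile.genotype,
        step_length_mean=jig(profile.step_length_mean),
        step_length_sigma=profile.step_length_sigma,
        turn_concentration=jig(profile.turn_concentration),
        uphill_bias=jig(profile.uphill_bias),
        elevation_preference=min(jig(profile.elevation_preference), 1.0),
        elevation_attraction=jig(profile.elevation_attraction),
        day_variability=jig(profile.day_variability),
    )


def _walk(
    profile: GenotypeProfile,
    terrain: TerrainModel,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Simulate one deployment; returns true positions, observed positions
    and the retained-fix mask.  Pure function of (profile, terrain, config,
    rng state)."""
    n_steps = config.fixes_per_day * config.days
    side = config.paddock_side_m
    e0, e1, n0, n1 = terrain.extent
    lo_e, hi_e = e0, min(e1, e0 + side)
    lo_n, hi_n = n0, min(n1, n0 + side)

    # pre-drawn randomness (keeps the sequential loop deterministic and lean)
    turn_noise = rng.standard_normal(n_steps)
    step_draws = rng.standard_normal(n_steps)
    gps_noise = rng.standard_normal((n_steps, 2)) * config.gps_noise_sd
    dropout_u = rng.random(n_steps)
    day_factor = np.exp(
        rng.standard_normal(config.days) * profile.day_variability
        - 0.5 * profile.day_variability**2
    )
    start = np.array([
        lo_e + rng.random() * (hi_e - lo_e),
        lo_n + rng.random() * (hi_n - lo_n),
    ])
    heading = rng.random() * 2 * np.pi

    kappa = profile.turn_concentration
    turn_sd = 0.0 if np.isinf(kappa) else (np.pi if kappa == 0 else 1.0 / np.sqrt(kappa))
    turn_sd = min(turn_sd, np.pi)
    # lognormal parametrized so the marginal step-length mean (over day
    # factors, which have unit mean) equals profile.step_length_mean
    mu = np.log(profile.step_length_mean) - 0.5 * profile.step_length_sigma**2

    z_lo = float(terrain.elevation.min())
    z_span = float(terrain.elevation.max() - terrain.elevation.min())
    pref_z = z_lo + profile.elevation_preference * z_span

    # local scalar state keeps the sequential loop cheap
    x, y = float(start[0]), float(start[1])
    true_pos = np.empty((n_steps, 2))
    steps_per_day = config.fixes_per_day
    dzdx, dzdy, zgrid = terrain._dzdx, terrain._dzdy, terrain.elevation
    oe, on, cs = terrain.origin_easting, terrain.origin_northing, terrain.cell_size
    n_rows, n_cols = terrain.n_rows, terrain.n_cols
    sigma = profile.step_length_sigma
    attract = profile.elevation_attraction
    uphill = profile.uphill_bias
    cos, sin, atan2, hypot, exp = math.cos, math.sin, math.atan2, math.hypot, math.exp
    for t in range(n_steps):
        day = t // steps_per_day
        c = int((x - oe) / cs)
        r = int((y - on) / cs)
        c = 0 if c < 0 else (n_cols - 1 if c >= n_cols else c)
        r = 0 if r < 0 else (n_rows - 1 if r >= n_rows else r)
        gx = dzdx[r, c]
        gy = dzdy[r, c]
        gnorm = hypot(gx, gy)
        dx = cos(heading)
        dy = sin(heading)
        if gnorm > 0:
            w = uphill * day_factor[day]
            if z_span > 0 and attract > 0:
                dz = pref_z - zgrid[r, c]
                pull = min(abs(dz) / (0.1 * z_span + 1e-9), 1.0)
                w += attract * pull * (1.0 if dz >= 0 else -1.0)
            dx += w * gx / gnorm
            dy += w * gy / gnorm
        heading = atan2(dy, dx) + turn_sd * turn_noise[t]
        step = exp(mu + sigma * step_draws[t]) * day_factor[day]
        x = _reflect(x + step * cos(heading), lo_e, hi_e)
        y = _reflect(y + step * sin(heading), lo_n, hi_n)
        true_pos[t, 0] = x
        true_pos[t, 1] = y
    observed = true_pos + gps_noise
    observed[:, 0] = np.clip(observed[:, 0], lo_e, hi_e - 1e-9)
    observed[:, 1] = np.clip(observed[:, 1], lo_n, hi_n - 1e-9)
    keep = dropout_u >= config.dropout_probability
    return true_pos, observed, keep


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        raise RuntimeError("degenerate paddock boundary")
    y = (x - lo) % (2 * span)
    y = span - abs(y - span)
    out = lo + y
    if out < lo or out > hi:
        raise RuntimeError("boundary reflection failed to keep position in paddock")
    return out


def simulate_trajectory(
    profile: GenotypeProfile,
    terrain: TerrainModel,
    config: SimulationConfig,
    seed,
    cow_id: str = "cow_0",
    farm_id: str = "farm_0",
) -> pd.DataFrame:
    """Simulate one cow deployment; returns a fix table (retained fixes only).

    Columns follow the package fix-table schema:
    ``cow_id, farm_id, genotype, timestamp_iso8601, easting_m, northing_m``.
    """
    rng = np.random.default_rng(seed)
    _, observed, keep = _walk(profile, terrain, config, rng)
    times = pd.date_range(
        config.start_date, periods=len(observed), freq=f"{config.fix_interval_s}s"
    )
    df = pd.DataFrame(
        {
            "cow_id": cow_id,
            "farm_id": farm_id,
            "genotype": profile.genotype,
            "timestamp_iso8601": times.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "easting_m": observed[:, 0],
            "northing_m": observed[:, 1],
        }
    )
    return df.loc[keep].reset_index(drop=True)


def farm_terrain(config: SimulationConfig, farm_index: int) -> TerrainModel:
    """The (deterministic) terrain of one farm under a simulation config."""
    return generate_terrain(
        np.random.SeedSequence((config.seed, 7919, farm_index)),
        extent=config.paddock_side_m,
        cell_size=config.cell_size,
        relief_amplitude=config.relief_amplitude,
        base_elevation=config.base_elevation + 50.0 * farm_index,
    )


def simulate_herd(
    profiles: list[GenotypeProfile],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, TerrainModel]]:
    """Simulate a multi-farm herd.

    Returns ``(fix_table, ground_truth, terrains)``: one fix table covering
    all cows, a ground-truth table mapping cow id to genotype, farm and the
    generative profile parameters, and the per-farm terrain models.
    Everything is a pure function of (profiles, config).
    """
    if config.n_farms < 1:
        raise ValueError("at least one farm required")
    fix_frames = []
    truth_rows = []
    terrains: dict[str, TerrainModel] = {}
    seen_ids: set[str] = set()
    for f in range(config.n_farms):
        farm_id = f"farm_{f}"
        terrain = farm_terrain(config, f)
        terrains[farm_id] = terrain
        cow_index = 0
        for profile in profiles:
            for _ in range(config.cows_per_genotype_per_farm):
                cow_id = f"{farm_id}_cow_{cow_index:03d}"
                if cow_id in seen_ids:
                    raise ValueError(f"duplicate cow id {cow_id}")
                seen_ids.add(cow_id)
                rng = _cow_stream(config.seed, f, cow_index)
                cow_profile = _individualize(profile, rng, config.individual_variation)
                _, observed, keep = _walk(cow_profile, terrain, config, rng)
                times = pd.date_range(
                    config.start_date,
                    periods=len(observed),
                    freq=f"{config.fix_interval_s}s",
                )
                fix_frames.append(
                    pd.DataFrame(
                        {
                            "cow_id": cow_id,
                            "farm_id": farm_id,
                            "genotype": profile.genotype,
                            "timestamp_iso8601": times.strftime("%Y-%m-%dT%H:%M:%SZ"),
                            "easting_m": observed[:, 0],
                            "northing_m": observed[:, 1],
                        }
                    ).loc[keep]
                )
                row = {"cow_id": cow_id, "farm_id": farm_id}
                row.update(asdict(cow_profile))
                truth_rows.append(row)
                cow_index += 1
    if not truth_rows:
        return (
            pd.DataFrame(columns=FIX_TABLE_COLUMNS),
            pd.DataFrame(columns=["cow_id", "farm_id", "genotype"]),
            terrains,
        )
    fixes = pd.concat(fix_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return fixes, truth, terrains
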