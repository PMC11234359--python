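"""Random-acceleration dissociation protocol on a reduced Langevin model.

The biasing protocol is the one used for protein-ligand egress simulations:
a force of constant magnitude and random direction acts on the ligand's
centre of mass; after every evaluation interval (100 fs by default) the
direction is retained if the centre of mass moved by more than a
displacement threshold (0.0025 nm), and redrawn uniformly on the unit
sphere otherwise.  The run stops when the centre-of-mass distance exceeds a
dissociation cutoff, or at a 40 ns cap.

Instead of an atomistic complex, the ligand here is a single Brownian
particle in three dimensions moving on a radial free-energy landscape with
a fully bound basin, a prebound basin and a confining funnel — enough
structure to reproduce the qualitative protocol phenomenology (forced
dissociation, metastable prebound dwells, loss of the intermediate at
extreme force) at desk scale.  The receptor is fixed at the origin.

Propagation is overdamped (Euler-Maruyama) Langevin dynamics; the inner
loop is JIT-compiled with numba and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

KB_KJ_PER_MOL_K = 0.0083144621

__all__ = [
    "ToyLandscape",
    "RAMDParams",
    "RAMDTrajectory",
    "draw_random_direction",
    "ramd_redirection_check",
    "run_ramd",
    "force_scan",
]


class IntegrationError(RuntimeError):
    """The integrator produced non-finite coordinates (unstable timestep)."""


@dataclass(frozen=True)
class ToyLandscape:
    """Radial free-energy landscape: Gaussian basins plus confining walls.

    ``U(r) = -sum_i depth_i * exp(-(r - center_i)^2 / (2 width_i^2))``
    plus half-harmonic walls below ``inner_wall_nm`` and above
    ``outer_wall_nm`` (the funnel that confines the dissociated state).
    Units: nm and kJ/mol.  Because the energy depends on r only, gradients
    and the Boltzmann radial density are available in closed form.
    """

    centers_nm: tuple[float, ...] = (2.65, 2.85)
    depths_kjmol: tuple[float, ...] = (180.0, 240.0)
    widths_nm: tuple[float, ...] = (0.040, 0.050)
    inner_wall_nm: float = 2.40
    outer_wall_nm: float = 3.60
    wall_k_kjmol_nm2: float = 50000.0

    def __post_init__(self) -> None:
        if not (len(self.centers_nm) == len(self.depths_kjmol) == len(self.widths_nm)):
            raise ValueError("centers, depths and widths must have equal length")
        if any(w <= 0 for w in self.widths_nm):
            raise ValueError("basin widths must be positive")
        if len(self.centers_nm) >= 2 and not all(
            a < b for a, b in zip(self.centers_nm, self.centers_nm[1:])
        ):
            raise ValueError("basin centers must be increasing")
        if self.centers_nm and self.centers_nm[-1] >= self.outer_wall_nm:
            raise ValueError("basins must lie inside the outer wall")

    def energy(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        u = np.zeros_like(r)
        for c, d, w in zip(self.centers_nm, self.depths_kjmol, self.widths_nm):
            u -= d * np.exp(-((r - c) ** 2) / (2 * w**2))
        u = u + np.where(r < self.inner_wall_nm,
                         0.5 * self.wall_k_kjmol_nm2 * (r - self.inner_wall_nm) ** 2, 0.0)
        u = u + np.where(r > self.outer_wall_nm,
                         0.5 * self.wall_k_kjmol_nm2 * (r - self.outer_wall_nm) ** 2, 0.0)
        return u

    def gradient(self, r: np.ndarray) -> np.ndarray:
        """dU/dr, closed form."""
        r = np.asarray(r, dtype=float)
        g = np.zeros_like(r)
        for c, d, w in zip(self.centers_nm, self.depths_kjmol, self.widths_nm):
            g += d * (r - c) / w**2 * np.exp(-((r - c) ** 2) / (2 * w**2))
        g = g + np.where(r < self.inner_wall_nm,
                         self.wall_k_kjmol_nm2 * (r - self.inner_wall_nm), 0.0)
        g = g + np.where(r > self.outer_wall_nm,
                         self.wall_k_kjmol_nm2 * (r - self.outer_wall_nm), 0.0)
        return g

    def max_restoring_force(self, r_lo: float | None = None, r_hi: float | None = None) -> float:
        """Max |dU/dr| on [r_lo, r_hi] (defaults: between the walls)."""
        lo = self.inner_wall_nm if r_lo is None else r_lo
        hi = self.outer_wall_nm if r_hi is None else r_hi
        grid = np.linspace(lo, hi, 20001)
        return float(np.abs(self.gradient(grid)).max())

    @classmethod
    def from_profile(cls, profile: dict) -> "ToyLandscape":
        return cls(
            centers_nm=tuple(profile["centers_nm"]),
            depths_kjmol=tuple(profile["depths_kjmol"]),
            widths_nm=tuple(profile["widths_nm"]),
            inner_wall_nm=profile["inner_wall_nm"],
            outer_wall_nm=profile["outer_wall_nm"],
            wall_k_kjmol_nm2=profile["wall_k_kjmol_nm2"],
        )

    @classmethod
    def default(cls) -> "ToyLandscape":
        """The calibrated two-basin landscape from the shipped profile."""
        from .config import load_profile

        return cls.from_profile(load_profile()["toy_landscape"])


@dataclass(frozen=True)
class RAMDParams:
    """Protocol and integrator parameters.

    The protocol values (force magnitude 3500 kJ/(mol nm), 100 fs
    evaluation interval, 0.0025 nm displacement threshold, 40 ns cap) are
    the study's; mass and friction set the Brownian mobility of the toy
    ligand and are calibration constants of the reduced model.
    """

    force_magnitude: float = 3500.0  # kJ/(mol nm)
    evaluation_interval_fs: float = 100.0
    displacement_threshold_nm: float = 0.0025
    max_time_ns: float = 40.0
    dissociation_cutoff_nm: float = 3.40
    timestep_fs: float = 2.0
    temperature_K: float = 300.0
    friction_per_ps: float = 10.0
    mass_amu: float = 6500.0
    seed: int = 0
    snapshot_ps: float = 2.0
    start_r_nm: float = 2.65

    def __post_init__(self) -> None:
        for name in (
            "evaluation_interval_fs", "max_time_ns", "dissociation_cutoff_nm",
            "timestep_fs", "temperature_K", "friction_per_ps", "mass_amu", "snapshot_ps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.force_magnitude < 0 or self.displacement_threshold_nm < 0:
            raise ValueError("force magnitude and displacement threshold must be non-negative")
        ratio = self.evaluation_interval_fs / self.timestep_fs
        if ratio < 1 or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "evaluation interval must be an integer multiple (>= 1) of the timestep"
            )

    @property
    def kt(self) -> float:
        return KB_KJ_PER_MOL_K * self.temperature_K

    @property
    def eval_steps(self) -> int:
        return int(round(self.evaluation_interval_fs / self.timestep_fs))


@dataclass
class RAMDTrajectory:
    """Per-snapshot log of one biased run."""

    times_ps: np.ndarray
    positions_nm: np.ndarray  # (n, 3) ligand COM
    r_nm: np.ndarray
    force_directions: np.ndarray  # (n, 3) unit vectors at snapshot times
    redirection_times_ps: np.ndarray
    dissociation_time_ns: float | None
    params: RAMDParams
    landscape: ToyLandscape

    @property
    def dissociated(self) -> bool:
        return self.dissociation_time_ns is not None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ps": self.times_ps,
                "r_nm": self.r_nm,
                "fx": self.force_directions[:, 0],
                "fy": self.force_directions[:, 1],
                "fz": self.force_directions[:, 2],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def draw_random_direction(rng: np.random.Generator) -> np.ndarray:
    """A direction uniform on the unit sphere (normalised Gaussian triple)."""
    while True:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            return v / norm


def ramd_redirection_check(
    com_now: np.ndarray, com_at_last_check: np.ndarray, threshold: float
) -> str:
    """'retain' iff the COM moved by strictly more than *threshold*, else 'redraw'."""
    if threshold < 0:
        raise ValueError("displacement threshold must be non-negative")
    displacement = float(np.linalg.norm(np.asarray(com_now, float) - np.asarray(com_at_last_check, float)))
    return "retain" if displacement > threshold else "redraw"


@njit(cache=True)
def _ramd_kernel(
    centers, depths, widths, inner_wall, outer_wall, wall_k,
    force_mag, eval_steps, disp_thresh2, n_steps, snap_steps,
    dt, kt, mgamma, diss_cutoff, seed, start_r,
):
    np.random.seed(seed)
    mobility = dt / mgamma
    sigma = np.sqrt(2.0 * kt * dt / mgamma)
    n_basins = centers.shape[0]

    n_snap_max = n_steps // snap_steps + 2
    snap_r = np.empty(n_snap_max)
    snap_pos = np.empty((n_snap_max, 3))
    snap_dir = np.empty((n_snap_max, 3))
    n_checks_max = n_steps // eval_steps + 2
    redirect_steps = np.empty(n_checks_max, dtype=np.int64)
    n_redirect = 0

    x = np.zeros(3)
    x[0] = start_r

    # initial direction chosen at random
    d = np.empty(3)
    nrm = 0.0
    while nrm < 1e-12:
        for k in range(3):
            d[k] = np.random.normal()
        nrm = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    for k in range(3):
        d[k] /= nrm
    redirect_steps[n_redirect] = 0
    n_redirect += 1

    last_check = x.copy()
    n_snap = 0
    diss_step = np.int64(-1)
    status = 0  # 0 = reached cap, 1 = dissociated, 2 = non-finite blow-up

    for step in range(n_steps + 1):
        r = np.sqrt(x[0] ** 2 + x[1] ** 2 + x[2] ** 2)
        if not np.isfinite(r):
            status = 2
            break
        if step % snap_steps == 0:
            snap_r[n_snap] = r
            for k in range(3):
                snap_pos[n_snap, k] = x[k]
                snap_dir[n_snap, k] = d[k]
            n_snap += 1
        if r > diss_cutoff:
            status = 1
            diss_step = step
            break
        if step == n_steps:
            break
        if step > 0 and step % eval_steps == 0:
            dx0 = x[0] - last_check[0]
            dx1 = x[1] - last_check[1]
            dx2 = x[2] - last_check[2]
            if dx0 * dx0 + dx1 * dx1 + dx2 * dx2 <= disp_thresh2:
                nrm = 0.0
                while nrm < 1e-12:
                    for k in range(3):
                        d[k] = np.random.normal()
                    nrm = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
                for k in range(3):
                    d[k] /= nrm
                redirect_steps[n_redirect] = step
                n_redirect += 1
            last_check[0] = x[0]
            last_check[1] = x[1]
            last_check[2] = x[2]

        # radial gradient of the landscape
        g = 0.0
        for i in range(n_basins):
            dr = r - centers[i]
            g += depths[i] * dr / widths[i] ** 2 * np.exp(-(dr * dr) / (2.0 * widths[i] ** 2))
        if r < inner_wall:
            g += wall_k * (r - inner_wall)
        elif r > outer_wall:
            g += wall_k * (r - outer_wall)

        inv_r = 1.0 / r if r > 1e-12 else 0.0
        for k in range(3):
            f = -g * x[k] * inv_r + force_mag * d[k]
            x[k] += mobility * f + sigma * np.random.normal()

    return snap_r[:n_snap], snap_pos[:n_snap], snap_dir[:n_snap], \
        redirect_steps[:n_redirect], diss_step, status


def run_ramd(landscape: ToyLandscape, params: RAMDParams) -> RAMDTrajectory:
    """Propagate one biased run and return its full event log.

    The run is bit-reproducible for a fixed ``params.seed``.  Raises
    :class:`IntegrationError` if the trajectory blows up (non-finite
    coordinates), which indicates the timestep is too large for the
    landscape stiffness.
    """
    dt_ps = params.timestep_fs * 1e-3
    n_steps = int(round(params.max_time_ns * 1e3 / dt_ps))
    snap_steps = max(int(round(params.snapshot_ps / dt_ps)), 1)
    snap_r, snap_pos, snap_dir, redirect_steps, diss_step, status = _ramd_kernel(
        np.asarray(landscape.centers_nm, dtype=float),
        np.asarray(landscape.depths_kjmol, dtype=float),
        np.asarray(landscape.widths_nm, dtype=float),
        landscape.inner_wall_nm,
        landscape.outer_wall_nm,
        landscape.wall_k_kjmol_nm2,
        params.force_magnitude,
        params.eval_steps,
        params.displacement_threshold_nm**2,
        n_steps,
        snap_steps,
        dt_ps,
        params.kt,
        params.mass_amu * params.friction_per_ps,
        params.dissociation_cutoff_nm,
        params.seed,
        params.start_r_nm,
    )
    if status == 2:
        raise IntegrationError(
            "non-finite coordinates during propagation; reduce the timestep"
        )
    times = np.arange(len(snap_r)) * snap_steps * dt_ps
    dissociation_time_ns = float(diss_step * dt_ps / 1e3) if status == 1 else None
    return RAMDTrajectory(
        times_ps=times,
        positions_nm=snap_pos,
        r_nm=snap_r,
        force_directions=snap_dir,
        redirection_times_ps=redirect_steps * dt_ps,
        dissociation_time_ns=dissociation_time_ns,
        params=params,
        landscape=landscape,
    )


def force_scan(
    landscape: ToyLandscape,
    magnitudes: Sequence[float],
    n_seeds: int,
    base_params: RAMDParams | None = None,
    thresholds=None,
    smoothing=None,
) -> pd.DataFrame:
    """Run paired-seed sets of biased runs over a list of force magnitudes.

    Returns one row per magnitude with the fraction of runs that dissociate,
    the fraction that visit the prebound band (>= 1 ns contiguous dwell of
    the smoothed r) and the median dissociation time, with non-dissociating
    runs entering the median as +inf (censoring at the cap).
    """
    from .state_analysis import SmoothingParams, StateThresholds, detect_prebound_visit, moving_average

    if len(magnitudes) < 2:
        raise ValueError("a force scan needs at least two magnitudes")
    base = base_params if base_params is not None else RAMDParams()
    thresholds = thresholds if thresholds is not None else StateThresholds()
    smoothing = smoothing if smoothing is not None else SmoothingParams()
    rows = []
    for magnitude in magnitudes:
        dissociated = 0
        visited = 0
        diss_times = []
        for seed_offset in range(n_seeds):
            params = replace(base, force_magnitude=float(magnitude), seed=base.seed + seed_offset)
            run = run_ramd(landscape, params)
            smoothed = moving_average(run.times_ps, run.r_nm, smoothing)
            report = detect_prebound_visit(run.times_ps, smoothed, thresholds)
            if run.dissociated:
                dissociated += 1
                diss_times.append(run.dissociation_time_ns)
            else:
                diss_times.append(np.inf)
            if report.visited_prebound:
                visited += 1
        rows.append(
            {
                "force_magnitude": float(magnitude),
                "fraction_dissociated": dissociated / n_seeds,
                "fraction_visited_prebound": visited / n_seeds,
                "median_dissociation_ns": float(np.median(diss_times)),
            }
        )
    return pd.DataFrame(rows)
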