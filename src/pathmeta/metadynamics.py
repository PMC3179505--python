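"""Metadynamics on the (S, Z) plane: deposition, bias forces, FES recovery.

A history-dependent bias is grown by depositing Gaussian hills at the
visited collective-variable values,

    V(s, z, t) = Σ_{t_k < t} h · exp(−(s−s_k)²/2σ_s²) · exp(−(z−z_k)²/2σ_z²),

with constant height h = deposition_rate × stride (standard, non-well-
tempered metadynamics).  At convergence the accumulated bias compensates
the underlying free energy, so F(s, z) ≈ −V(s, z, t) up to a constant;
the stopping criterion is the recrossing event — the system, having
reached the product region of S, returns to the reactant region.

Inside the integrator the bias force is looked up on a fine grid that is
updated analytically at each deposition (spacing σ/5, bilinear
interpolation); :func:`bias_value` and :func:`bias_gradient` evaluate the
exact Gaussian sums and are the reference the engine is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels as K
from .core import Configuration, Trajectory
from .pathcv import Frameset, PathCV
from .toy_models import (
    IntegrationError,
    LangevinParams,
    Potential,
    _effective_masses,
    maxwell_boltzmann_velocities,
)
from .units import kt

__all__ = [
    "MetadConfig",
    "HillLog",
    "FreeEnergySurface",
    "CartesianCV",
    "bias_value",
    "bias_gradient",
    "run_metadynamics",
    "reconstruct_fes",
    "detect_recrossing",
    "MetadResult",
]


@dataclass(frozen=True)
class MetadConfig:
    """Gaussian deposition settings.

    Defaults: rate 0.1 kcal mol⁻¹ ps⁻¹ deposited every 1 ps (hill height
    0.1 kcal mol⁻¹) with widths 0.15 S-units and 0.20 Å² in Z.
    """

    deposition_rate: float = 0.1
    stride: float = 1.0
    sigma_s: float = 0.15
    sigma_z: float = 0.20

    def __post_init__(self):
        if self.deposition_rate < 0:
            raise ValueError("deposition_rate must be >= 0")
        if self.stride <= 0 or self.sigma_s <= 0 or self.sigma_z <= 0:
            raise ValueError("stride and widths must be positive")

    @property
    def hill_height(self) -> float:
        return self.deposition_rate * self.stride


class HillLog:
    """Time-stamped Gaussian deposits; sufficient statistic for the FES."""

    def __init__(self, times, s, z, height, sigma_s, sigma_z):
        self.times = np.asarray(times, dtype=float)
        self.s = np.asarray(s, dtype=float)
        self.z = np.asarray(z, dtype=float)
        n = len(self.times)
        self.height = np.broadcast_to(np.asarray(height, dtype=float), (n,)).copy()
        self.sigma_s = np.broadcast_to(np.asarray(sigma_s, dtype=float), (n,)).copy()
        self.sigma_z = np.broadcast_to(np.asarray(sigma_z, dtype=float), (n,)).copy()
        if len(self.s) != n or len(self.z) != n:
            raise ValueError("hill columns must have equal length")
        if n > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("hill times must be non-decreasing")
        if np.any(self.height < 0):
            raise ValueError("hill heights must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def total_height(self) -> float:
        return float(self.height.sum())

    @property
    def span(self) -> float:
        return float(self.times[-1]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "s": self.s,
                "z": self.z,
                "sigma_s": self.sigma_s,
                "sigma_z": self.sigma_z,
                "height": self.height,
            }
        )

    def save(self, path: str | Path) -> None:
        """Whitespace table (time, s, z, sigma_s, sigma_z, height)."""
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write("#! FIELDS " + " ".join(df.columns) + "\n")
            for row in df.itertuples(index=False):
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "HillLog":
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            names=["time", "s", "z", "sigma_s", "sigma_z", "height"],
        )
        return cls(
            df["time"], df["s"], df["z"], df["height"], df["sigma_s"], df["sigma_z"]
        )


def _hill_weights(hills: HillLog, t: float, average_from: float | None) -> np.ndarray:
    """Per-hill weight in the (possibly time-averaged) bias at time t."""
    if average_from is None or average_from >= t:
        return (hills.times < t).astype(float)
    # mean over tau in [average_from, t] of 1[t_k < tau]
    span = t - average_from
    return np.clip((t - np.maximum(hills.times, average_from)) / span, 0.0, 1.0) * (
        hills.times < t
    )


def bias_value(s, z, hills: HillLog, t: float) -> np.ndarray | float:
    """Exact metadynamics bias V(s, z, t) summed over hills older than t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    s = np.asarray(s, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(hills) == 0:
        return np.zeros(np.broadcast(s, z).shape) if s.ndim or z.ndim else 0.0
    w = _hill_weights(hills, t, None) * hills.height
    es = np.exp(
        -((s[..., None] - hills.s) ** 2) / (2.0 * hills.sigma_s**2)
    )
    ez = np.exp(
        -((z[..., None] - hills.z) ** 2) / (2.0 * hills.sigma_z**2)
    )
    out = (w * es * ez).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def bias_gradient(s, z, hills: HillLog, t: float):
    """Analytic (∂V/∂s, ∂V/∂z) of the exact Gaussian sum."""
    s = np.asarray(s, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(hills) == 0:
        zero = np.zeros(np.broadcast(s, z).shape)
        return zero, zero.copy()
    w = _hill_weights(hills, t, None) * hills.height
    ds = s[..., None] - hills.s
    dz = z[..., None] - hills.z
    g = w * np.exp(-(ds**2) / (2.0 * hills.sigma_s**2)) * np.exp(
        -(dz**2) / (2.0 * hills.sigma_z**2)
    )
    gs = (-g * ds / hills.sigma_s**2).sum(axis=-1)
    gz = (-g * dz / hills.sigma_z**2).sum(axis=-1)
    if gs.ndim == 0:
        return float(gs), float(gz)
    return gs, gz


@dataclass
class FreeEnergySurface:
    """F(s, z) on a regular grid, kcal mol⁻¹, global minimum at zero."""

    s_grid: np.ndarray
    z_grid: np.ndarray
    values: np.ndarray  # (ns, nz)
    isoline_spacing: float = 1.0

    def __post_init__(self):
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.s_grid), len(self.z_grid)):
            raise ValueError("values shape must be (len(s_grid), len(z_grid))")

    def profile_along_s(self, kind: str = "min", temperature: float = 300.0):
        """1D free-energy profile F(s).

        ``min``: minimum over z per s-column.  ``marginal``: proper
        Boltzmann marginalisation over z at the given temperature.
        Returned shifted to min 0.
        """
        if kind == "min":
            prof = self.values.min(axis=1)
        elif kind == "marginal":
            kT = kt(temperature)
            dz = np.gradient(self.z_grid)
            w = np.exp(-self.values / kT) * dz
            prof = -kT * np.log(np.maximum(w.sum(axis=1), 1e-300))
        else:
            raise ValueError("kind must be 'min' or 'marginal'")
        return prof - prof.min()

    def to_frame(self) -> pd.DataFrame:
        ss, zz = np.meshgrid(self.s_grid, self.z_grid, indexing="ij")
        return pd.DataFrame(
            {"s": ss.ravel(), "z": zz.ravel(), "free_energy": self.values.ravel()}
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot(self, path: str | Path | None = None, max_level: float | None = None):
        """Contour plot with isolines every ``isoline_spacing`` kcal mol⁻¹."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        top = max_level or float(np.nanmax(self.values))
        levels = np.arange(0.0, top + self.isoline_spacing, self.isoline_spacing)
        fig, ax = plt.subplots(figsize=(6, 4))
        cs = ax.contourf(self.s_grid, self.z_grid, self.values.T, levels=levels)
        ax.contour(
            self.s_grid,
            self.z_grid,
            self.values.T,
            levels=levels,
            colors="k",
            linewidths=0.4,
        )
        fig.colorbar(cs, ax=ax, label="F / kcal mol$^{-1}$")
        ax.set_xlabel("S")
        ax.set_ylabel("Z / $\\mathrm{\\AA}^2$")
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
            return None
        return fig


def reconstruct_fes(
    hills: HillLog,
    t: float,
    s_grid: np.ndarray | None = None,
    z_grid: np.ndarray | None = None,
    average_from: float | None = None,
) -> FreeEnergySurface:
    """F(s, z) = −V(s, z, t), shifted so the global minimum is zero.

    When ``average_from`` is given, −V is averaged uniformly over
    deposition times in [average_from, t], which damps the O(hill height)
    ripple of a single snapshot.  An empty log yields a flat zero surface.
    With no explicit grid, axes cover all hill centers ± 4σ at σ/5 spacing.
    """
    if s_grid is None or z_grid is None:
        if len(hills) == 0:
            raise ValueError("cannot infer a grid from an empty hill log")
        ss = hills.sigma_s.max()
        sz = hills.sigma_z.max()
        if s_grid is None:
            s_grid = np.arange(
                hills.s.min() - 4 * ss, hills.s.max() + 4 * ss + ss / 5, ss / 5
            )
        if z_grid is None:
            z_grid = np.arange(
                hills.z.min() - 4 * sz, hills.z.max() + 4 * sz + sz / 5, sz / 5
            )
    s_grid = np.asarray(s_grid, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    if len(hills) == 0:
        return FreeEnergySurface(s_grid, z_grid, np.zeros((len(s_grid), len(z_grid))))
    w = _hill_weights(hills, t, average_from) * hills.height
    es = np.exp(
        -((s_grid[:, None] - hills.s[None, :]) ** 2) / (2.0 * hills.sigma_s**2)
    )
    ez = np.exp(
        -((z_grid[:, None] - hills.z[None, :]) ** 2) / (2.0 * hills.sigma_z**2)
    )
    v = np.einsum("sk,zk,k->sz", es, ez, w)
    f = -v
    f -= f.min()
    return FreeEnergySurface(s_grid, z_grid, f)


def detect_recrossing(s_series, start_region, end_region, times=None):
    """First return to the start region after having reached the end region.

    Regions are disjoint closed S-intervals (lo, hi).  Returns the time
    (or the index, when ``times`` is None) of the qualifying return, or
    None if the series never recrosses.
    """
    lo1, hi1 = start_region
    lo2, hi2 = end_region
    if hi1 < lo1 or hi2 < lo2:
        raise ValueError("regions must be ordered (lo, hi)")
    if not (hi1 < lo2 or hi2 < lo1):
        raise ValueError("start and end regions must be disjoint")
    s = np.asarray(s_series, dtype=float)
    in_start = (s >= lo1) & (s <= hi1)
    in_end = (s >= lo2) & (s <= hi2)
    end_hits = np.flatnonzero(in_end)
    if len(end_hits) == 0:
        return None
    first_end = end_hits[0]
    returns = np.flatnonzero(in_start[first_end + 1 :])
    if len(returns) == 0:
        return None
    idx = first_end + 1 + returns[0]
    return float(times[idx]) if times is not None else int(idx)


class CartesianCV:
    """Use two Cartesian coordinates (atom, axis) directly as the (S, Z) pair."""

    mode = 0

    def __init__(self, atom_s=0, axis_s=0, atom_z=0, axis_z=1):
        self.atoms = np.array([atom_s, atom_z], dtype=np.int64)
        self.axes = np.array([axis_s, axis_z], dtype=np.int64)


@dataclass
class MetadResult:
    """Outcome of a metadynamics run; unpacks as (trajectory, hills)."""

    trajectory: Trajectory
    hills: HillLog
    s: np.ndarray
    z: np.ndarray
    recrossing_time: float | None = None
    final_coords: np.ndarray | None = None

    def __iter__(self):
        return iter((self.trajectory, self.hills))


def run_metadynamics(
    potential: Potential,
    start: Configuration,
    params: LangevinParams,
    cv,
    config: MetadConfig = MetadConfig(),
    *,
    max_time: float = 10000.0,
    grid=None,
    z_wall: float | None = None,
    z_wall_k: float = 10.0,
    stop_on_recross=None,
    save_stride: int | None = None,
    chunk_time: float = 100.0,
) -> MetadResult:
    """Metadynamics in the canonical ensemble until recrossing (or max_time).

    ``cv`` is a :class:`~pathmeta.pathcv.Frameset`, a
    :class:`~pathmeta.pathcv.PathCV` or a :class:`CartesianCV`.  A hill of
    height ``deposition_rate × stride`` is deposited every ``stride`` ps
    at the current (S, Z); the bias force enters the dynamics through the
    chain rule via the CV gradients.  ``stop_on_recross`` is a pair of
    disjoint S-intervals ((lo, hi), (lo, hi)); the run stops at the end of
    the chunk in which the recrossing event is detected.  ``z_wall`` adds
    a one-sided harmonic restraint confining Z (useful to keep the sampled
    region compact).  Fixed seeds make the hill log bit-reproducible.
    """
    if isinstance(cv, Frameset):
        cv = PathCV(cv)
    dt = params.timestep
    stride_steps = max(1, int(round(config.stride / dt)))
    if save_stride is None:
        save_stride = max(1, int(round(0.5 / dt)))
    chunk_steps = max(stride_steps, int(round(chunk_time / dt)))
    chunk_steps -= chunk_steps % stride_steps or 0
    lcm = np.lcm(stride_steps, save_stride)
    chunk_steps = max(lcm, (chunk_steps // lcm) * lcm)
    max_steps = int(round(max_time / dt))

    if cv.mode == 1:
        fsd = cv.frameset
        frames = fsd.coords
        align_idx = fsd.align_selection
        disp_idx = fsd.displace_selection
        lam = fsd.lam
        cv_atoms = np.zeros(2, dtype=np.int64)
        cv_axes = np.array([0, 1], dtype=np.int64)
        if grid is None:
            zmax = (z_wall + 4 * config.sigma_z) if z_wall is not None else 12.0
            # Z >= -ln(P)/lambda by construction; cover that floor
            zmin = -math.log(fsd.P) / fsd.lam - 4 * config.sigma_z
            grid = (0.0, fsd.P + 1.0, zmin, zmax)
    else:
        frames = np.zeros((2, start.n_atoms, 3))
        align_idx = np.arange(3, dtype=np.int64)
        disp_idx = np.arange(1, dtype=np.int64)
        lam = 1.0
        cv_atoms = cv.atoms
        cv_axes = cv.axes
        if grid is None:
            raise ValueError("grid=(smin, smax, zmin, zmax) is required for CartesianCV")
    smin, smax, zmin, zmax = map(float, grid)
    ds = config.sigma_s / 5.0
    dz = config.sigma_z / 5.0
    ns = int(math.ceil((smax - smin) / ds)) + 1
    nz = int(math.ceil((zmax - zmin) / dz)) + 1
    fs_grid = np.zeros((ns, nz))
    fz_grid = np.zeros((ns, nz))

    n_hill_max = max_steps // stride_steps + 2
    hills_t = np.zeros(n_hill_max)
    hills_s = np.zeros(n_hill_max)
    hills_z = np.zeros(n_hill_max)

    coords = np.array(start.coordinates, dtype=float)
    meff = _effective_masses(start)
    rng = np.random.default_rng(params.seed)
    vel = maxwell_boltzmann_velocities(start, params.temperature, rng)
    K.seed_rng(params.seed % 2**31)

    all_xs = []
    all_s = []
    all_z = []
    n_hills = 0
    step0 = 0
    recross_t = None
    while step0 < max_steps:
        nsteps = min(chunk_steps, max_steps - step0)
        nsteps -= nsteps % stride_steps or 0
        if nsteps <= 0:
            nsteps = max_steps - step0
        n_save = (step0 + nsteps) // save_stride - step0 // save_stride
        xs = np.empty((max(n_save, 1), start.n_atoms, 3))
        s_out = np.empty(max(n_save, 1))
        z_out = np.empty(max(n_save, 1))
        n_hills, nsaved = K.metad_run(
            potential.kernel,
            potential.fargs,
            potential.iargs,
            coords,
            vel,
            meff,
            kt(params.temperature),
            params.friction,
            dt,
            nsteps,
            step0,
            cv.mode,
            cv_atoms,
            cv_axes,
            frames,
            align_idx,
            disp_idx,
            lam,
            config.hill_height,
            stride_steps,
            config.sigma_s,
            config.sigma_z,
            smin,
            ds,
            zmin,
            dz,
            fs_grid,
            fz_grid,
            z_wall_k if z_wall is not None else -1.0,
            z_wall if z_wall is not None else 0.0,
            hills_t,
            hills_s,
            hills_z,
            n_hills,
            save_stride,
            xs,
            s_out,
            z_out,
        )
        if n_hills < 0:
            raise IntegrationError(-n_hills - 1)
        step0 += nsteps
        all_xs.append(xs[:nsaved])
        all_s.append(s_out[:nsaved])
        all_z.append(z_out[:nsaved])
        if stop_on_recross is not None:
            s_all = np.concatenate(all_s)
            t_all = save_stride * dt * np.arange(1, len(s_all) + 1)
            recross_t = detect_recrossing(
                s_all, stop_on_recross[0], stop_on_recross[1], t_all
            )
            if recross_t is not None:
                break

    s_series = np.concatenate(all_s)
    z_series = np.concatenate(all_z)
    xs_all = (
        np.concatenate(all_xs)
        if all_xs
        else np.empty((0, start.n_atoms, 3))
    )
    times = save_stride * dt * np.arange(1, len(xs_all) + 1)
    traj = Trajectory(xs_all, start.elements, start.names, start.groups, times)
    hills = HillLog(
        hills_t[:n_hills],
        hills_s[:n_hills],
        hills_z[:n_hills],
        np.full(n_hills, config.hill_height),
        np.full(n_hills, config.sigma_s),
        np.full(n_hills, config.sigma_z),
    )
    return MetadResult(traj, hills, s_series, z_series, recross_t, coords)
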