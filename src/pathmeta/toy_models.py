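"""Analytic toy potentials, a BAOAB Langevin integrator, and fixture builders.

These desk-scale systems stand in for the all-atom protein/ligand/solvent
physics the sampling methods are normally applied to: a 1D double well
with a known free-energy profile (the reconstruction oracle), and a
funnel-shaped binding pocket — a spherical shell cavity with a Gaussian
binding well at its centre, a mouth channel opening to a confined bulk
region, optional purely repulsive solvent beads, and an optional narrow
"back-door" channel at the pocket bottom through which only solvent can
pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .core import Configuration, Trajectory
from .units import MASS_TO_KCAL, kt, mass_of

__all__ = [
    "Potential",
    "LangevinParams",
    "ToyPocketSpec",
    "double_well_1d",
    "harmonic_well",
    "linear_slope",
    "build_toy_pocket",
    "run_langevin",
    "maxwell_boltzmann_velocities",
]


class Potential:
    """A differentiable potential over (N, 3) coordinates in Å.

    ``energy`` returns kcal mol⁻¹ and ``gradient`` kcal mol⁻¹ Å⁻¹.  The
    heavy lifting is delegated to a numba kernel so that the same object
    can be passed to the fused integrator loops.  ``analytic_free_energy``,
    when set, is the closed-form free-energy profile along the potential's
    natural coordinate.
    """

    def __init__(self, kernel, fargs, iargs, dim, analytic_free_energy=None, meta=None):
        self.kernel = kernel
        self.fargs = np.asarray(fargs, dtype=float)
        self.iargs = np.asarray(iargs, dtype=np.int64)
        self.dim = dim
        self.analytic_free_energy = analytic_free_energy
        self.meta = meta or {}

    def _coords(self, x) -> np.ndarray:
        if isinstance(x, Configuration):
            x = x.coordinates
        return np.ascontiguousarray(x, dtype=float)

    def energy(self, x) -> float:
        coords = self._coords(x)
        grad = np.zeros_like(coords)
        return float(self.kernel(coords, self.fargs, self.iargs, grad))

    def gradient(self, x) -> np.ndarray:
        coords = self._coords(x)
        grad = np.zeros_like(coords)
        self.kernel(coords, self.fargs, self.iargs, grad)
        return grad

    def energy_and_gradient(self, x):
        coords = self._coords(x)
        grad = np.zeros_like(coords)
        e = float(self.kernel(coords, self.fargs, self.iargs, grad))
        return e, grad


@dataclass(frozen=True)
class LangevinParams:
    """Thermostat settings: 300 K and a 5 ps⁻¹ damping coefficient by
    default, with a 2 fs integration step."""

    temperature: float = 300.0
    friction: float = 5.0
    timestep: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")


@dataclass(frozen=True)
class ToyPocketSpec:
    """Geometry and composition of the synthetic funnel pocket.

    pocket_depth   binding-well depth, kcal mol⁻¹
    channel_length pocket-centre → bulk distance (shell radius), Å
    n_solvent      number of repulsive solvent beads in the bulk shell
    backdoor       open a narrow solvent-only channel at the pocket bottom
    ligand_atoms   beads in the rigid ligand (≥ 3 for well-posed fits)
    """

    pocket_depth: float = 6.0
    channel_length: float = 8.0
    n_solvent: int = 20
    backdoor: bool = False
    ligand_atoms: int = 4
    bulk_width: float = 9.0

    def __post_init__(self):
        if self.pocket_depth <= 0:
            raise ValueError("pocket_depth must be positive")
        if self.ligand_atoms < 3:
            raise ValueError("need at least 3 ligand atoms")
        if self.channel_length <= 0 or self.bulk_width <= 0:
            raise ValueError("geometry lengths must be positive")
        if self.n_solvent < 0:
            raise ValueError("n_solvent must be non-negative")


def double_well_1d(
    barrier: float, separation: float, transverse_k: float = 10.0
) -> Potential:
    """Symmetric quartic double well V(x) = barrier·((2x/sep)² − 1)².

    Minima at x = ±separation/2 with V = 0 and V(0) = barrier.  The y and
    z directions are harmonically confined (``transverse_k``) so that the
    particle's motion stays effectively one-dimensional; on the x axis the
    free-energy profile equals V itself.
    """
    if barrier <= 0 or separation <= 0:
        raise ValueError("barrier and separation must be positive")

    def fes(x):
        x = np.asarray(x, dtype=float)
        return barrier * ((2.0 * x / separation) ** 2 - 1.0) ** 2

    return Potential(
        K.dw1d_eg,
        [barrier, separation, transverse_k],
        [0],
        dim=1,
        analytic_free_energy=fes,
        meta={"barrier": barrier, "separation": separation},
    )


def harmonic_well(k: float, centers: np.ndarray) -> Potential:
    """Isotropic harmonic wells of stiffness k around per-atom centers."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    return Potential(
        K.harmonic_eg,
        np.concatenate([[k], centers.ravel()]),
        [0],
        dim=3 * len(centers),
        analytic_free_energy=None,
        meta={"k": k},
    )


def linear_slope(g: float, transverse_k: float = 10.0) -> Potential:
    """V = g·x for a single particle; ΔF over a distance d is exactly g·d."""
    return Potential(
        K.linear_eg,
        [g, transverse_k],
        [0],
        dim=1,
        analytic_free_energy=lambda x: g * np.asarray(x, dtype=float),
        meta={"g": g},
    )


# Funnel-pocket construction ------------------------------------------------

_POCKET_DEFAULTS = dict(
    k_int=200.0,  # stiff ligand bonds (rigid-body stand-in)
    sigma_well=2.0,
    wall_w=1.5,
    k_wall=25.0,
    mouth_half_angle=0.6,  # rad (ligand)
    mouth_half_angle_solvent=0.38,
    backdoor_half_angle=0.35,
    dcos=0.10,
    eps_wca=0.2,
    sigma_wca=2.8,
    k_funnel=25.0,
    rho_cyl=2.0,
    rho_pocket=3.5,
    z_floor=-2.5,
    rho_bulk=2.2,
    k_tether=100.0,
    ref_radius=2.0,
    ref_z=-3.0,
    ligand_edge=1.6,
)


def _ligand_geometry(n: int, edge: float) -> np.ndarray:
    """Compact ligand bead cluster: a tetrahedron, extended along z if n > 4."""
    tet = (
        np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
            dtype=float,
        )
        * edge
        / (2.0 * math.sqrt(2.0))
    )
    pts = [tet[i % 4] + np.array([0.0, 0.0, edge * (i // 4)]) for i in range(n)]
    pts = np.array(pts)
    return pts - pts.mean(axis=0)


def build_toy_pocket(
    spec: ToyPocketSpec, seed: int = 0, max_retries: int = 200
) -> tuple[Potential, Configuration]:
    """Build the funnel-pocket potential and a bound initial configuration.

    The configuration carries groups ``ligand_heavy``, ``pocket_ref`` (a
    tethered, non-interacting 4-bead reference cage near the pocket
    bottom) and ``water_O`` (solvent beads, placed in the bulk shell with
    overlap rejection).  The potential energy of the returned state is
    ≈ −pocket_depth (ligand centred in the binding well, everything else
    relaxed).
    """
    d = _POCKET_DEFAULTS
    n_lig = spec.ligand_atoms
    n_ref = 4
    n_sol = spec.n_solvent
    r_shell = spec.channel_length
    r_cont = r_shell + spec.bulk_width
    z_cap = r_cont
    z_cone = r_shell

    lig = _ligand_geometry(n_lig, d["ligand_edge"])
    ref_sites = np.array(
        [
            [d["ref_radius"], 0.0, d["ref_z"]],
            [-d["ref_radius"], 0.0, d["ref_z"]],
            [0.0, d["ref_radius"], d["ref_z"]],
            [0.0, -d["ref_radius"], d["ref_z"]],
        ]
    )

    rng = np.random.default_rng(seed)
    solvent = np.empty((n_sol, 3))
    placed = 0
    tries = 0
    while placed < n_sol:
        tries += 1
        if tries > max_retries * max(1, n_sol):
            raise RuntimeError(
                f"could not place {n_sol} solvent beads without overlap "
                f"after {tries} attempts"
            )
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        lo = r_shell + d["wall_w"] + 0.3
        hi = max(r_cont - 0.3, lo + 0.2)
        cand = u * (lo + rng.random() * (hi - lo))
        if placed and np.min(np.linalg.norm(solvent[:placed] - cand, axis=1)) < 2.6:
            continue
        solvent[placed] = cand
        placed += 1

    coords = np.vstack([lig, ref_sites, solvent]) if n_sol else np.vstack([lig, ref_sites])
    elements = ["C"] * n_lig + ["N"] * n_ref + ["O"] * n_sol
    names = (
        [f"L{i + 1}" for i in range(n_lig)]
        + [f"R{i + 1}" for i in range(n_ref)]
        + [f"OW{i + 1}" for i in range(n_sol)]
    )
    groups = {
        "ligand_heavy": np.arange(n_lig),
        "pocket_ref": np.arange(n_lig, n_lig + n_ref),
        "water_O": np.arange(n_lig + n_ref, n_lig + n_ref + n_sol),
    }
    config = Configuration(coords, elements, names, groups)

    bond_r0 = []
    for i in range(n_lig):
        for j in range(i + 1, n_lig):
            bond_r0.append(np.linalg.norm(lig[i] - lig[j]))
    fargs = np.concatenate(
        [
            [
                d["k_int"],
                spec.pocket_depth,
                d["sigma_well"],
                r_shell,
                d["wall_w"],
                d["k_wall"],
                math.cos(d["mouth_half_angle"]),
                math.cos(d["backdoor_half_angle"]),
                d["dcos"],
                d["eps_wca"],
                d["sigma_wca"],
                r_cont,
                d["k_funnel"],
                d["rho_cyl"],
                z_cap,
                z_cone,
                d["k_tether"],
                d["rho_pocket"],
                d["z_floor"],
                d["rho_bulk"],
                math.cos(d["mouth_half_angle_solvent"]),
            ],
            ref_sites.ravel(),
            bond_r0,
        ]
    )
    iargs = [n_lig, n_ref, n_sol, 1 if spec.backdoor else 0]
    pot = Potential(
        K.pocket_eg,
        fargs,
        iargs,
        dim=3 * config.n_atoms,
        meta={"spec": spec, "r_shell": r_shell, "r_cont": r_cont},
    )
    return pot, config


# Integration ---------------------------------------------------------------


def _effective_masses(config: Configuration) -> np.ndarray:
    return config.masses * MASS_TO_KCAL


def maxwell_boltzmann_velocities(
    config: Configuration, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Velocities (Å ps⁻¹) drawn from the Maxwell–Boltzmann distribution."""
    meff = _effective_masses(config)
    sd = np.sqrt(kt(temperature) / meff)
    return rng.normal(size=(config.n_atoms, 3)) * sd[:, None]


class IntegrationError(RuntimeError):
    def __init__(self, step: int):
        super().__init__(f"non-finite energy/force encountered at step {step}")
        self.step = step


def run_langevin(
    potential: Potential,
    start: Configuration,
    params: LangevinParams,
    n_steps: int,
    bias=None,
    save_stride: int = 1,
    velocities: np.ndarray | None = None,
    return_state: bool = False,
):
    """BAOAB-discretised Langevin dynamics.

    ``bias``, when given, is called as ``bias(t_ps, coords) -> forces`` and
    its return value (kcal mol⁻¹ Å⁻¹, shape (N, 3)) is added to the
    physical forces; this is the hook used by steering and metadynamics
    wrappers and by user code.  A fixed ``params.seed`` makes the run
    bit-reproducible.  Frames are recorded every ``save_stride`` steps.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    coords = np.array(start.coordinates, dtype=float)
    meff = _effective_masses(start)
    kT = kt(params.temperature)
    rng = np.random.default_rng(params.seed)
    v = (
        maxwell_boltzmann_velocities(start, params.temperature, rng)
        if velocities is None
        else np.array(velocities, dtype=float)
    )
    K.seed_rng(params.seed % 2**31)
    dt = params.timestep

    if bias is None:
        n_save = n_steps // save_stride
        xs = np.empty((n_save, start.n_atoms, 3))
        ret = K.baoab_run(
            potential.kernel,
            potential.fargs,
            potential.iargs,
            coords,
            v,
            meff,
            kT,
            params.friction,
            dt,
            n_steps,
            save_stride,
            xs,
        )
        if ret < 0:
            raise IntegrationError(-ret - 1)
        times = dt * save_stride * np.arange(1, n_save + 1)
    else:
        # generic python-callback path: same BAOAB splitting, same noise
        # stream (drawn through the shared numba RNG), suitable for short
        # exploratory runs.
        c1 = math.exp(-params.friction * dt)
        c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
        sd = np.sqrt(kT / meff)[:, None]
        g = potential.gradient(coords) - bias(0.0, coords)
        frames = []
        for step in range(n_steps):
            v -= 0.5 * dt * g / meff[:, None]
            coords += 0.5 * dt * v
            noise = K.draw_normal_block(coords.shape[0])
            v = c1 * v + c2 * sd * noise
            coords += 0.5 * dt * v
            t = (step + 1) * dt
            e, g = potential.energy_and_gradient(coords)
            if not np.isfinite(e):
                raise IntegrationError(step)
            g = g - bias(t, coords)
            v -= 0.5 * dt * g / meff[:, None]
            if (step + 1) % save_stride == 0:
                frames.append(coords.copy())
        xs = np.array(frames) if frames else np.empty((0, start.n_atoms, 3))
        times = dt * save_stride * np.arange(1, len(xs) + 1)

    traj = Trajectory(xs, start.elements, start.names, start.groups, times)
    if return_state:
        return traj, coords, v
    return traj
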