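"""Self-validation studies on toy systems with independently known answers.

Two benchmark systems exercise the whole stack end to end:

* a confined 1D double well, whose free-energy profile *is* the potential
  — metadynamics on the particle's (x, y) coordinates must recover the
  well-to-well ΔF (= 0) and the barrier height;

* the funnel pocket, where the full protocol (equilibrate → five steered
  expulsions → lowest-work selection → frameset → path-CV metadynamics)
  is compared against a long unbiased run: with a 6 kcal mol⁻¹ well and
  a light thermostat (1 ps⁻¹) the unbiased trajectory performs dozens of
  binding/unbinding round trips in a few hundred ns, so −kT·ln p(S) is a
  genuine independent estimate of the free-energy profile along the path.

Both legs of the pocket comparison use the same estimator: the
Boltzmann marginal over Z of F(S, Z), minimum-to-minimum between the
bound and unbound S-windows.  All functions derive their stage seeds
from one base seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metadynamics import CartesianCV, MetadConfig, reconstruct_fes, run_metadynamics
from .pathcv import Frameset, evaluate_path_cv_batch, extract_frameset
from .steering import PullRecord, SMDConfig, run_smd, select_lowest_work
from .toy_models import (
    Configuration,
    LangevinParams,
    Potential,
    ToyPocketSpec,
    build_toy_pocket,
    double_well_1d,
    run_langevin,
)
from .units import kt

__all__ = [
    "double_well_fes_study",
    "PocketStudy",
    "build_pocket_study",
    "pocket_unbiased_profile",
    "pocket_metad_delta_g",
    "BOUND_WINDOW",
    "UNBOUND_WINDOW",
]

#: S-windows (in frame-index units, frameset of P = 12) used for the
#: bound and unbound states of the toy pocket.
BOUND_WINDOW = (1.0, 5.0)
UNBOUND_WINDOW = (8.0, 11.8)

_DT = 0.004  # ps; toy systems are soft enough for a 4 fs step


def double_well_fes_study(
    seed: int = 0,
    n_seeds: int = 3,
    barrier: float = 6.0,
    separation: float = 2.0,
    sim_time: float = 8000.0,
    temperature: float = 300.0,
):
    """Metadynamics reconstruction of the double-well profile.

    Runs ``n_seeds`` independent simulations biasing the particle's
    (x, y) coordinates, reconstructs F(x) = min_y F(x, y) from the
    time-averaged bias, and reads off the well-to-well ΔF and the barrier
    relative to the left well.  Returns a dict with per-seed values and
    their means; the analytic answers are ΔF = 0 and barrier = ``barrier``.
    """
    pot = double_well_1d(barrier, separation)
    x0 = -separation / 2.0
    start = Configuration(np.array([[x0, 0.0, 0.0]]), ["C"])
    half = separation / 2.0
    s_grid = np.linspace(-separation, separation, 321)
    z_grid = np.linspace(-1.0, 1.0, 81)
    config = MetadConfig(
        deposition_rate=0.1, stride=1.0, sigma_s=0.1, sigma_z=0.12
    )
    dfs, barriers, hill_logs = [], [], []
    for k in range(n_seeds):
        params = LangevinParams(temperature, 5.0, _DT, seed + 101 + k)
        res = run_metadynamics(
            pot,
            start,
            params,
            CartesianCV(0, 0, 0, 1),
            config,
            max_time=sim_time,
            grid=(-separation - 0.5, separation + 0.5, -1.5, 1.5),
            save_stride=int(round(1.0 / _DT)),
        )
        fes = reconstruct_fes(
            res.hills, res.hills.span, s_grid, z_grid,
            average_from=0.5 * res.hills.span,
        )
        prof = fes.profile_along_s("min")
        x = fes.s_grid
        left = prof[np.abs(x + half) <= 0.4].min()
        right = prof[np.abs(x - half) <= 0.4].min()
        top = prof[np.abs(x) <= 0.3].max()
        dfs.append(right - left)
        barriers.append(top - left)
        hill_logs.append(res.hills)
    return {
        "delta_f": float(np.mean(dfs)),
        "barrier": float(np.mean(barriers)),
        "delta_f_per_seed": dfs,
        "barrier_per_seed": barriers,
        "analytic_barrier": barrier,
        "hills": hill_logs,
        "potential": pot,
        "s_grid": s_grid,
        "z_grid": z_grid,
    }


@dataclass
class PocketStudy:
    """The seeded pipeline front half: system, pulls, chosen path."""

    potential: Potential
    start: Configuration
    equilibrated: Configuration
    records: list[PullRecord]
    selected: PullRecord
    frameset: Frameset


def build_pocket_study(
    seed: int = 0,
    depth: float = 6.0,
    n_solvent: int = 0,
    frameset_p: int = 12,
    pull_speed: float = 0.04,
    pull_extension: float = 16.0,
) -> PocketStudy:
    """Equilibrate the bound pocket, run five steered expulsions, select
    the lowest-work run and extract the frameset from it.

    The pull extends the ligand–anchor distance by 16 Å, i.e. from the
    binding well through the mouth to the end of the solvent vestibule,
    so the frameset spans the full bound → unbound transition.
    """
    spec = ToyPocketSpec(pocket_depth=depth, n_solvent=n_solvent)
    pot, cfg = build_toy_pocket(spec, seed=seed + 1)
    lp_eq = LangevinParams(300.0, 5.0, _DT, seed + 11)
    eq = run_langevin(pot, cfg, lp_eq, 5000, save_stride=5000)
    eqc = cfg.with_coordinates(eq.coords[-1])
    smd_conf = SMDConfig(
        "ligand_heavy", "pocket_ref", 20.0, pull_speed, pull_extension
    )
    records, trajs = [], {}
    for r in range(5):
        rec, traj = run_smd(
            pot,
            eqc,
            LangevinParams(300.0, 5.0, _DT, seed + 100 + r),
            smd_conf,
            run_id=r,
            record_stride=50,
            save_stride=50,
            return_trajectory=True,
        )
        records.append(rec)
        trajs[r] = traj
    chosen = select_lowest_work(records)
    frameset = extract_frameset(
        trajs[chosen.run_id], frameset_p, "pocket_ref", "ligand_heavy"
    )
    return PocketStudy(pot, cfg, eqc, records, chosen, frameset)


def _window_min(s_axis, profile, window):
    mask = (s_axis >= window[0]) & (s_axis <= window[1]) & np.isfinite(profile)
    return float(profile[mask].min())


def pocket_unbiased_profile(
    study: PocketStudy,
    seed: int = 0,
    sim_time: float = 600000.0,
    friction: float = 1.0,
    temperature: float = 300.0,
    s_bin: float = 0.25,
):
    """Histogram free-energy profile along S from one long unbiased run.

    Returns (delta_g, centers, profile, n_round_trips).  The light
    friction accelerates barrier crossing without changing equilibrium
    populations, so the histogram is an independent oracle for the
    metadynamics estimate.
    """
    n_steps = int(round(sim_time / _DT))
    traj = run_langevin(
        study.potential,
        study.equilibrated,
        LangevinParams(temperature, friction, _DT, seed + 77),
        n_steps,
        save_stride=100,
    )
    s, _ = evaluate_path_cv_batch(traj.coords, study.frameset)
    p_tot = study.frameset.P
    edges = np.arange(0.75, p_tot + 0.76, s_bin)
    hist, _ = np.histogram(s, bins=edges)
    centers = 0.5 * (edges[1:] + edges[:-1])
    kT = kt(temperature)
    with np.errstate(divide="ignore"):
        prof = -kT * np.log(hist / hist.sum())
    prof -= _window_min(centers, prof, BOUND_WINDOW)
    mid = 0.5 * (BOUND_WINDOW[1] + UNBOUND_WINDOW[0])
    unbound = s > mid
    round_trips = int(np.sum(np.abs(np.diff(unbound.astype(int)))) // 2)
    dg = _window_min(centers, prof, UNBOUND_WINDOW)
    return dg, centers, prof, round_trips


def pocket_metad_delta_g(
    study: PocketStudy,
    seed: int = 0,
    n_seeds: int = 3,
    sim_time: float = 20000.0,
    friction: float = 1.0,
    temperature: float = 300.0,
):
    """Path-CV metadynamics estimate of the pocket binding ΔG.

    Each seed deposits hills for ``sim_time`` ps (the toy recrossing
    event happens long before the surface is filled, so a fixed
    deposition time with tail-averaged bias replaces the recrossing stop
    here); ΔG is min-to-min between the unbound and bound windows of the
    Z-marginalised profile, averaged over seeds.
    """
    fs = study.frameset
    config = MetadConfig(deposition_rate=0.1, stride=1.0, sigma_s=0.3, sigma_z=0.8)
    dgs = []
    for k in range(n_seeds):
        res = run_metadynamics(
            study.potential,
            study.equilibrated,
            LangevinParams(temperature, friction, _DT, seed + 21 + k),
            fs,
            config,
            max_time=sim_time,
            grid=(0.0, fs.P + 1.0, -12.0, 30.0),
            save_stride=50,
            chunk_time=1000.0,
        )
        fes = reconstruct_fes(
            res.hills, res.hills.span, average_from=0.5 * res.hills.span
        )
        prof = fes.profile_along_s("marginal", temperature)
        prof = prof - _window_min(fes.s_grid, prof, BOUND_WINDOW)
        dgs.append(_window_min(fes.s_grid, prof, UNBOUND_WINDOW))
    return float(np.mean(dgs)), dgs
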