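"""Constant-velocity steered dynamics along a COM–COM distance coordinate.

A harmonic guide U(t) = ½·k·(ξ − ξ₀ − v·t)² is dragged at constant speed
along ξ, the distance between the mass-weighted centres of two atom
groups (pulled ligand vs. pocket anchor).  The applied force
F(t) = k·(ξ₀ + v·t − ξ) and the accumulated nonequilibrium work
W(t) = ∫ F·v dt (trapezoid rule on the integration grid) are recorded;
repeated realisations differ only in their initial Maxwell–Boltzmann
velocities, and the lowest-work run seeds the path definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels as K
from .core import Configuration, Trajectory
from .toy_models import (
    IntegrationError,
    LangevinParams,
    Potential,
    _effective_masses,
    maxwell_boltzmann_velocities,
)
from .units import kt

__all__ = [
    "SMDConfig",
    "PullRecord",
    "schedule_duration",
    "run_smd",
    "select_lowest_work",
]


@dataclass(frozen=True)
class SMDConfig:
    """Pulling protocol: groups, spring constant, speed and extension.

    Defaults follow the standard slow-growth regime for ligand expulsion:
    a 20 kcal mol⁻¹ Å⁻² spring moved at 0.005 Å ps⁻¹.
    """

    group_a: object  # pulled selection (name or indices)
    group_b: object  # anchor selection (or None with anchor_point)
    force_constant: float = 20.0
    speed: float = 0.005
    target_extension: float = 7.5
    anchor_point: tuple | None = None  # fixed reference instead of group_b

    def __post_init__(self):
        if self.group_b is None and self.anchor_point is None:
            raise ValueError("need either group_b or anchor_point")
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.target_extension < 0:
            raise ValueError("target_extension must be non-negative")


@dataclass
class PullRecord:
    """Time series of one steered run: ξ, guide centre, force and work."""

    times: np.ndarray
    xi: np.ndarray
    restraint_center: np.ndarray
    force: np.ndarray
    work: np.ndarray
    run_id: int = 0

    def __post_init__(self):
        n = len(self.times)
        for name in ("xi", "restraint_center", "force", "work"):
            if len(getattr(self, name)) != n:
                raise ValueError("all series must have equal length")

    @property
    def final_work(self) -> float:
        return float(self.work[-1])

    @property
    def force_total_variation(self) -> float:
        return float(np.sum(np.abs(np.diff(self.force))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "xi": self.xi,
                "center": self.restraint_center,
                "force": self.force,
                "work": self.work,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def load(cls, path: str | Path, run_id: int = 0) -> "PullRecord":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["t"].to_numpy(),
            df["xi"].to_numpy(),
            df["center"].to_numpy(),
            df["force"].to_numpy(),
            df["work"].to_numpy(),
            run_id,
        )


def schedule_duration(config: SMDConfig) -> float:
    """Pull duration in ps: target_extension / speed.

    At the default 0.005 Å ps⁻¹, a 7.5 Å extension takes 1500 ps (1.5 ns).
    """
    if config.speed == 0:
        raise ValueError("speed must be nonzero")
    return config.target_extension / config.speed


def run_smd(
    potential: Potential,
    start: Configuration,
    params: LangevinParams,
    config: SMDConfig,
    run_id: int = 0,
    record_stride: int = 1,
    save_stride: int = 0,
    return_trajectory: bool = False,
    equilibration_ps: float = 5.0,
):
    """One constant-velocity steered realisation.

    Initial velocities are a fresh Maxwell–Boltzmann draw from
    ``params.seed`` (re-seeding realisations is the way to generate
    independent pulls).  Before the centre starts moving, the system is
    relaxed for ``equilibration_ps`` under the static restraint, so the
    recorded work is measured from the equilibrated guided ensemble.
    Returns the :class:`PullRecord`, plus the saved trajectory when
    ``return_trajectory`` (requires ``save_stride > 0``).
    """
    ga = start.select(config.group_a).astype(np.int64)
    if config.group_b is not None:
        gb = start.select(config.group_b).astype(np.int64)
        if len(gb) == 0:
            raise ValueError("pull groups must be non-empty")
        if set(ga.tolist()) & set(gb.tolist()):
            raise ValueError("pull groups must be disjoint")
        anchor = np.zeros(3)
    else:
        gb = np.empty(0, dtype=np.int64)
        anchor = np.asarray(config.anchor_point, dtype=float)
    if len(ga) == 0:
        raise ValueError("pull groups must be non-empty")

    duration = schedule_duration(config)
    n_steps = max(1, int(round(duration / params.timestep)))
    coords = np.array(start.coordinates, dtype=float)
    meff = _effective_masses(start)
    rng = np.random.default_rng(params.seed)
    v = maxwell_boltzmann_velocities(start, params.temperature, rng)
    K.seed_rng(params.seed % 2**31)

    wa = meff[ga] / meff[ga].sum()
    com_a = (wa[:, None] * coords[ga]).sum(axis=0)
    if len(gb):
        wb = meff[gb] / meff[gb].sum()
        com_b = (wb[:, None] * coords[gb]).sum(axis=0)
    else:
        com_b = anchor
    xi0 = float(np.linalg.norm(com_a - com_b))
    if xi0 < 1e-9:
        raise ValueError("reaction coordinate undefined (coincident COMs)")

    n_eq = int(round(equilibration_ps / params.timestep))
    if n_eq > 0:
        dummy = np.empty(2)
        ret, _ = K.smd_run(
            potential.kernel,
            potential.fargs,
            potential.iargs,
            coords,
            v,
            meff,
            kt(params.temperature),
            params.friction,
            params.timestep,
            n_eq,
            ga,
            gb,
            anchor,
            config.force_constant,
            0.0,
            xi0,
            n_eq,
            np.empty(3),
            np.empty(3),
            np.empty(3),
            np.empty(3),
            np.empty(3),
            np.empty((0, start.n_atoms, 3)),
            0,
        )
        if ret < 0:
            raise IntegrationError(-ret - 1)

    n_rec = n_steps // record_stride + 1
    t_out = np.empty(n_rec)
    xi_out = np.empty(n_rec)
    c_out = np.empty(n_rec)
    f_out = np.empty(n_rec)
    w_out = np.empty(n_rec)
    n_save = n_steps // save_stride if save_stride > 0 else 0
    xs = np.empty((n_save, start.n_atoms, 3))

    nrec, nsaved = K.smd_run(
        potential.kernel,
        potential.fargs,
        potential.iargs,
        coords,
        v,
        meff,
        kt(params.temperature),
        params.friction,
        params.timestep,
        n_steps,
        ga,
        gb,
        anchor,
        config.force_constant,
        config.speed,
        xi0,
        record_stride,
        t_out,
        xi_out,
        c_out,
        f_out,
        w_out,
        xs,
        save_stride,
    )
    if nrec < 0:
        if nrec == -1 and nsaved == 0 and n_steps > 0:
            # distinguish undefined coordinate at t=0 from late divergence
            raise ValueError("reaction coordinate undefined (coincident COMs)")
        raise IntegrationError(-nrec - 1)
    record = PullRecord(
        t_out[:nrec], xi_out[:nrec], c_out[:nrec], f_out[:nrec], w_out[:nrec], run_id
    )
    if return_trajectory:
        times = params.timestep * save_stride * np.arange(1, nsaved + 1)
        traj = Trajectory(xs[:nsaved], start.elements, start.names, start.groups, times)
        return record, traj
    return record


def select_lowest_work(records: list[PullRecord]) -> PullRecord:
    """The realisation with minimal final work.

    Ties (within 1e-9 kcal mol⁻¹) are broken by the smoother force profile
    (lower total variation), then by run_id.
    """
    if not records:
        raise ValueError("no pull records given")
    n = len(records[0].times)
    if any(len(r.times) != n for r in records):
        raise ValueError("records have different schedules")
    return min(
        records,
        key=lambda r: (round(r.final_work, 9), round(r.force_total_variation, 9), r.run_id),
    )
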