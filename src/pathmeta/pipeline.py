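"""End-to-end orchestration of the unbinding-sampling protocol.

One call runs the whole sequence on a configured system: short
equilibration, five steered expulsion runs with re-initialised
velocities, lowest-work run selection, frameset extraction and λ
calibration, path-CV metadynamics until the recrossing event, and the
closing analyses (FES time evolution, basins, hydration map).  Every
stage writes its artifacts into a fixed directory layout and a manifest
records config hash, seeds and versions; reruns with the same config and
seeds reproduce the hill log bitwise.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import SegmentAxis, SwitchingParams, basin_delta_g, find_basins, hydration_map
from .core import Configuration, write_pdb_minimal, write_xyz
from .metadynamics import MetadConfig, reconstruct_fes, run_metadynamics
from .pathcv import Frameset, evaluate_path_cv_batch, extract_frameset
from .steering import PullRecord, SMDConfig, run_smd, select_lowest_work
from .toy_models import LangevinParams, ToyPocketSpec, build_toy_pocket, run_langevin

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run (YAML-friendly)."""

    system: dict = field(
        default_factory=lambda: dict(
            type="toy_pocket",
            pocket_depth=6.0,
            channel_length=8.0,
            n_solvent=20,
            backdoor=False,
            ligand_atoms=4,
        )
    )
    langevin: dict = field(
        default_factory=lambda: dict(temperature=300.0, friction=5.0, timestep=0.004)
    )
    equilibration_ps: float = 20.0
    smd: dict = field(
        default_factory=lambda: dict(
            force_constant=20.0, speed=0.005, target_extension=7.5, n_runs=5
        )
    )
    frameset_p: int = 18
    metad: dict = field(
        default_factory=lambda: dict(
            deposition_rate=0.1,
            stride=1.0,
            sigma_s=0.15,
            sigma_z=0.20,
            max_time=2000.0,
            z_wall=8.0,
        )
    )
    analysis: dict = field(
        default_factory=lambda: dict(min_depth=1.0, fes_checkpoints=5, s_bin=0.5)
    )
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f: raw[f] for f in raw if f in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _build_system(config: PipelineConfig):
    sysconf = dict(config.system)
    kind = sysconf.pop("type", "toy_pocket")
    if kind != "toy_pocket":
        raise PipelineError("system", f"unsupported system type {kind!r}")
    spec = ToyPocketSpec(**sysconf)
    return build_toy_pocket(spec, seed=config.seed)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(outdir)
    for sub in ("pulls", "path", "hills", "fes", "analysis", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "pathmeta",
        "version": __version__,
        "config_sha256": config.digest(),
        "seed": config.seed,
        "stages": [],
        "config": config.to_dict(),
    }
    t0 = time.time()

    def done(stage: str, **info):
        manifest["stages"].append(
            {"stage": stage, "elapsed_s": round(time.time() - t0, 3), **info}
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    lp = LangevinParams(seed=config.seed, **config.langevin)

    # --- system construction
    try:
        potential, start = _build_system(config)
        write_pdb_minimal(out / "logs" / "system.pdb", start)
        write_xyz(out / "logs" / "system.xyz", start)
    except Exception as exc:
        raise PipelineError("system", str(exc)) from exc
    done("system", n_atoms=start.n_atoms)

    # --- equilibration
    try:
        n_eq = max(1, int(round(config.equilibration_ps / lp.timestep)))
        eq_traj = run_langevin(potential, start, lp, n_eq, save_stride=max(1, n_eq // 10))
        eq = start.with_coordinates(eq_traj.coords[-1])
    except Exception as exc:
        raise PipelineError("equilibrate", str(exc)) from exc
    done("equilibrate", steps=n_eq)

    # --- steered runs
    try:
        smd_conf = dict(config.smd)
        n_runs = int(smd_conf.pop("n_runs", 5))
        smd = SMDConfig(group_a="ligand_heavy", group_b="pocket_ref", **smd_conf)
        records: list[PullRecord] = []
        trajs = {}
        for run in range(n_runs):
            seed_i = config.seed + 1000 + run
            rec, traj = run_smd(
                potential,
                eq,
                LangevinParams(lp.temperature, lp.friction, lp.timestep, seed_i),
                smd,
                run_id=run,
                record_stride=max(1, int(round(1.0 / lp.timestep))),
                save_stride=max(1, int(round(1.0 / lp.timestep))),
                return_trajectory=True,
            )
            rec.save(out / "pulls" / f"run_{run}.tsv")
            records.append(rec)
            trajs[run] = traj
        chosen = select_lowest_work(records)
        write_xyz(out / "pulls" / f"run_{chosen.run_id}.xyz", trajs[chosen.run_id])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("smd", str(exc)) from exc
    done(
        "smd",
        works=[round(r.final_work, 4) for r in records],
        selected_run=chosen.run_id,
    )

    # --- frameset
    try:
        frameset = extract_frameset(
            trajs[chosen.run_id], config.frameset_p, "pocket_ref", "ligand_heavy"
        )
        frameset.save(out / "path" / "frameset")
    except Exception as exc:
        raise PipelineError("frameset", str(exc)) from exc
    done(
        "frameset",
        P=frameset.P,
        lam=round(frameset.lam, 4),
        mean_spacing=float(np.mean(frameset.adjacent_msd)),
    )

    # --- metadynamics
    try:
        mconf = dict(config.metad)
        max_time = float(mconf.pop("max_time", 2000.0))
        z_wall = mconf.pop("z_wall", None)
        mc = MetadConfig(**mconf)
        p = frameset.P
        result = run_metadynamics(
            potential,
            eq,
            lp,
            frameset,
            mc,
            max_time=max_time,
            z_wall=z_wall,
            stop_on_recross=((1.0, 1.0 + 0.15 * (p - 1)), (p - 0.15 * (p - 1), float(p))),
        )
        result.hills.save(out / "hills" / "hills.dat")
        np.savetxt(
            out / "hills" / "s_series.tsv",
            np.column_stack([result.trajectory.times, result.s, result.z]),
            header="t s z",
            fmt="%.8g",
        )
    except Exception as exc:
        raise PipelineError("metadynamics", str(exc)) from exc
    done(
        "metadynamics",
        n_hills=len(result.hills),
        simulated_ps=float(result.hills.span),
        recrossing_ps=result.recrossing_time,
    )

    # --- analysis
    try:
        span = result.hills.span
        ncheck = int(config.analysis.get("fes_checkpoints", 5))
        checkpoints = np.linspace(span / ncheck, span, ncheck)
        fes = None
        for tc in checkpoints:
            fes = reconstruct_fes(result.hills, tc)
            fes.save(out / "fes" / f"fes_{tc:.0f}ps.tsv")
            fes.plot(out / "fes" / f"fes_{tc:.0f}ps.png")
        basins = find_basins(fes, config.analysis.get("min_depth", 1.0))
        basin_info = [
            {
                "label": b.label,
                "s": round(b.minimum[0], 3),
                "z": round(b.minimum[1], 3),
                "depth": round(b.depth, 3),
            }
            for b in basins
        ]
        dg = None
        if len(basins) >= 2:
            dg = basin_delta_g(fes, basins[0], basins[-1])
        axis = SegmentAxis(np.array([0.0, 0.0, -3.0]), np.array([0.0, 0.0, 8.0]))
        s_frames, _ = evaluate_path_cv_batch(result.trajectory.coords, frameset)
        if len(result.trajectory.groups.get("water_O", [])):
            grid, edges = hydration_map(
                result.trajectory,
                s_frames,
                axis,
                SwitchingParams(),
                config.analysis.get("s_bin", 0.5),
            )
            np.savetxt(out / "analysis" / "hydration_map.tsv", grid, fmt="%.6g")
        (out / "analysis" / "basins.json").write_text(
            json.dumps({"basins": basin_info, "delta_g_first_last": dg}, indent=2)
        )
    except Exception as exc:
        raise PipelineError("analysis", str(exc)) from exc
    done("analysis", n_basins=len(basins))
    return manifest
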