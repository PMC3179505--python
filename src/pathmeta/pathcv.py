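"""Path collective variables: superposition, MSD metric, framesets, S and Z.

The progression variable S(R) and the distance variable Z(R) map a
configuration R onto a reference sequence of P configurations (the
*frameset*) through the mean-squared-deviation metric after least-squares
superposition:

    S = Σ_{i=1..P} i·exp(−λ·D_i) / Σ_i exp(−λ·D_i)
    Z = −(1/λ)·ln Σ_i exp(−λ·D_i)

where D_i is the MSD (Å²) between R and frame i, computed by rigid-body
superposition on an *alignment* selection (a stable reference cage) and
measured over a *displacement* selection (the ligand heavy atoms).  S is
1-indexed, so a converged run spans [1, P]; Z is in Å².  λ (Å⁻²) controls
how sharply neighbouring frames are weighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import _kernels as K
from .core import Configuration, Trajectory, read_xyz, write_xyz

__all__ = [
    "Frameset",
    "PathCVValue",
    "superpose",
    "msd_distance",
    "extract_frameset",
    "calibrate_lambda",
    "evaluate_path_cv",
    "evaluate_path_cv_batch",
    "PathCV",
]


class DegenerateFitError(ValueError):
    """Alignment selection too small or collinear for a rigid-body fit."""


def _check_alignment(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError("need at least 3 alignment atoms")
    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-8 * max(1.0, sv[0]):
        raise DegenerateFitError("alignment atoms are (nearly) collinear")


def _kearsley_batch(mob: np.ndarray, ref: np.ndarray):
    """Batched Kearsley fit: mob, ref of shape (..., m, 3).

    Returns (rot, cm, cr) with rot @ (p - cm) + cr the optimal mapping of
    mobile points onto the reference, and the per-pair alignment MSD.
    """
    cm = mob.mean(axis=-2)
    cr = ref.mean(axis=-2)
    a = mob - cm[..., None, :]
    b = ref - cr[..., None, :]
    d = a - b
    s = a + b
    dx, dy, dz = d[..., 0], d[..., 1], d[..., 2]
    sx, sy, sz = s[..., 0], s[..., 1], s[..., 2]

    def acc(v):
        return v.sum(axis=-1)

    km = np.empty(mob.shape[:-2] + (4, 4))
    km[..., 0, 0] = acc(dx * dx + dy * dy + dz * dz)
    km[..., 1, 1] = acc(dx * dx + sy * sy + sz * sz)
    km[..., 2, 2] = acc(sx * sx + dy * dy + sz * sz)
    km[..., 3, 3] = acc(sx * sx + sy * sy + dz * dz)
    km[..., 0, 1] = km[..., 1, 0] = acc(sy * dz - sz * dy)
    km[..., 0, 2] = km[..., 2, 0] = acc(sz * dx - sx * dz)
    km[..., 0, 3] = km[..., 3, 0] = acc(sx * dy - sy * dx)
    km[..., 1, 2] = km[..., 2, 1] = acc(dx * dy - sx * sy)
    km[..., 1, 3] = km[..., 3, 1] = acc(dx * dz - sx * sz)
    km[..., 2, 3] = km[..., 3, 2] = acc(dy * dz - sy * sz)
    w, v = np.linalg.eigh(km)
    q = v[..., :, 0]
    q1, q2, q3, q4 = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    rot = np.empty(mob.shape[:-2] + (3, 3))
    rot[..., 0, 0] = q1 * q1 + q2 * q2 - q3 * q3 - q4 * q4
    rot[..., 1, 0] = 2.0 * (q2 * q3 + q1 * q4)
    rot[..., 2, 0] = 2.0 * (q2 * q4 - q1 * q3)
    rot[..., 0, 1] = 2.0 * (q2 * q3 - q1 * q4)
    rot[..., 1, 1] = q1 * q1 + q3 * q3 - q2 * q2 - q4 * q4
    rot[..., 2, 1] = 2.0 * (q3 * q4 + q1 * q2)
    rot[..., 0, 2] = 2.0 * (q2 * q4 + q1 * q3)
    rot[..., 1, 2] = 2.0 * (q3 * q4 - q1 * q2)
    rot[..., 2, 2] = q1 * q1 + q4 * q4 - q2 * q2 - q3 * q3
    fit_msd = np.maximum(w[..., 0], 0.0) / mob.shape[-2]
    return rot, cm, cr, fit_msd


def superpose(mobile, reference, align_selection):
    """Optimal rigid-body superposition (Kearsley quaternion method).

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile coordinates onto the
    reference; rmsd (Å) is minimized over the alignment selection.
    """
    xm = mobile.coordinates if isinstance(mobile, Configuration) else np.asarray(mobile)
    xr = (
        reference.coordinates
        if isinstance(reference, Configuration)
        else np.asarray(reference)
    )
    idx = (
        mobile.select(align_selection)
        if isinstance(mobile, Configuration)
        else np.asarray(align_selection, dtype=np.intp)
    )
    _check_alignment(xm[idx])
    rot, cm, cr, fit_msd = _kearsley_batch(xm[idx], xr[idx])
    translation = cr - rot @ cm
    return rot, translation, float(math.sqrt(fit_msd))


def msd_distance(a, b, align_selection, displace_selection) -> float:
    """MSD (Å²) over the displacement atoms after fitting on the alignment
    atoms.  Symmetric in its arguments when the selections coincide."""
    xa = a.coordinates if isinstance(a, Configuration) else np.asarray(a)
    xb = b.coordinates if isinstance(b, Configuration) else np.asarray(b)
    ai = (
        a.select(align_selection)
        if isinstance(a, Configuration)
        else np.asarray(align_selection, dtype=np.intp)
    )
    di = (
        a.select(displace_selection)
        if isinstance(a, Configuration)
        else np.asarray(displace_selection, dtype=np.intp)
    )
    if len(di) == 0:
        raise ValueError("displace selection is empty")
    rot, t, _ = superpose(xa, xb, ai)
    moved = xa[di] @ rot.T + t
    return float(np.mean(np.sum((moved - xb[di]) ** 2, axis=1)))


@dataclass
class Frameset:
    """Ordered reference configurations defining the path space."""

    coords: np.ndarray  # (P, N, 3)
    elements: list[str]
    align_selection: np.ndarray
    displace_selection: np.ndarray
    lam: float
    adjacent_msd: np.ndarray

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        self.align_selection = np.asarray(self.align_selection, dtype=np.int64)
        self.displace_selection = np.asarray(self.displace_selection, dtype=np.int64)
        self.adjacent_msd = np.asarray(self.adjacent_msd, dtype=float)
        if self.coords.shape[0] < 2:
            raise ValueError("a frameset needs at least two frames")
        if len(self.align_selection) == 0 or len(self.displace_selection) == 0:
            raise ValueError("selections must be non-empty")
        if np.any(self.adjacent_msd <= 0):
            raise ValueError("adjacent MSDs must be positive")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def P(self) -> int:
        return self.coords.shape[0]

    def save(self, prefix: str | Path) -> None:
        """Write frames as multi-frame XYZ plus a YAML sidecar."""
        prefix = Path(prefix)
        traj = Trajectory(self.coords, self.elements)
        write_xyz(prefix.with_suffix(".xyz"), traj)
        sidecar = {
            "align_selection": self.align_selection.tolist(),
            "displace_selection": self.displace_selection.tolist(),
            "lambda": float(self.lam),
            "adjacent_msd": self.adjacent_msd.tolist(),
        }
        prefix.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))

    @classmethod
    def load(cls, prefix: str | Path) -> "Frameset":
        prefix = Path(prefix)
        traj = read_xyz(prefix.with_suffix(".xyz"))
        try:
            meta = yaml.safe_load(prefix.with_suffix(".yaml").read_text())
        except yaml.YAMLError as exc:
            raise ValueError(f"corrupt frameset sidecar {prefix}.yaml: {exc}") from exc
        try:
            return cls(
                traj.coords,
                traj.elements,
                np.asarray(meta["align_selection"]),
                np.asarray(meta["displace_selection"]),
                float(meta["lambda"]),
                np.asarray(meta["adjacent_msd"]),
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"corrupt frameset sidecar {prefix}.yaml: {exc}") from exc


@dataclass
class PathCVValue:
    """S (dimensionless, in [1, P]), Z (Å²) and their coordinate gradients.

    Gradients are full (N, 3) arrays, nonzero only on the displacement
    selection (the optimal rotation is treated as fixed per evaluation).
    """

    s: float
    z: float
    ds_dx: np.ndarray
    dz_dx: np.ndarray


def pairwise_msd_matrix(
    coords: np.ndarray, align_idx: np.ndarray, disp_idx: np.ndarray, block: int = 20000
) -> np.ndarray:
    """Full symmetric matrix of MSD distances between the given frames."""
    n = coords.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    out = np.zeros((n, n))
    for lo in range(0, len(ii), block):
        sl = slice(lo, lo + block)
        i, j = ii[sl], jj[sl]
        rot, cm, cr, _ = _kearsley_batch(coords[i][:, align_idx], coords[j][:, align_idx])
        moved = np.einsum("bcd,bkd->bkc", rot, coords[i][:, disp_idx] - cm[:, None, :])
        moved += cr[:, None, :]
        d = np.mean(np.sum((moved - coords[j][:, disp_idx]) ** 2, axis=2), axis=1)
        out[i, j] = d
        out[j, i] = d
    return out


def extract_frameset(
    traj: Trajectory,
    P: int,
    align_selection,
    displace_selection,
    lam: float | None = None,
    max_candidates: int = 400,
) -> Frameset:
    """Select P frames (first and last always kept) with near-even spacing.

    Even spacing is obtained by dynamic programming over a candidate grid
    (at most ``max_candidates`` frames, evenly subsampled), minimising the
    squared deviation of adjacent MSDs from their running target — the
    automated analogue of choosing neighbour configurations as evenly
    distributed as possible along the transition.
    """
    if len(traj) < P:
        raise ValueError(f"trajectory has {len(traj)} frames, needs >= {P}")
    if P < 2:
        raise ValueError("P must be >= 2")
    tmp = Configuration(traj.coords[0], traj.elements, traj.names, traj.groups)
    align_idx = tmp.select(align_selection).astype(np.int64)
    disp_idx = tmp.select(displace_selection).astype(np.int64)
    _check_alignment(traj.coords[0][align_idx])

    if len(traj) > max_candidates:
        cand = np.unique(
            np.round(np.linspace(0, len(traj) - 1, max_candidates)).astype(int)
        )
    else:
        cand = np.arange(len(traj))
    coords = np.ascontiguousarray(traj.coords[cand])
    nc = len(cand)
    dmat = pairwise_msd_matrix(coords, align_idx, disp_idx)
    if dmat[0, -1] < 1e-10:
        raise ValueError("trajectory has no net displacement; no path to extract")
    if P == len(traj):
        sel = np.arange(len(traj))
        frames = np.ascontiguousarray(traj.coords[sel])
        adj = np.array(
            [
                msd_distance(frames[k], frames[k + 1], align_idx, disp_idx)
                for k in range(P - 1)
            ]
        )
        lam_val = lam if lam is not None else calibrate_lambda(adj)
        return Frameset(frames, traj.elements, align_idx, disp_idx, lam_val, adj)

    # iterate target spacing: start from the even-index selection
    sel_c = np.round(np.linspace(0, nc - 1, P)).astype(int)
    target = float(np.mean(dmat[sel_c[:-1], sel_c[1:]]))
    big = 1e30
    for _ in range(3):
        cost = np.full((P, nc), big)
        parent = np.zeros((P, nc), dtype=int)
        cost[0, 0] = 0.0
        for p in range(1, P):
            for j in range(p, nc):
                prev = cost[p - 1, :j] + (dmat[:j, j] - target) ** 2
                i = int(np.argmin(prev))
                cost[p, j] = prev[i]
                parent[p, j] = i
        sel_c = np.empty(P, dtype=int)
        sel_c[-1] = nc - 1
        for p in range(P - 1, 0, -1):
            sel_c[p - 1] = parent[p, sel_c[p]]
        target = float(np.mean(dmat[sel_c[:-1], sel_c[1:]]))

    sel = cand[sel_c]
    frames = np.ascontiguousarray(traj.coords[sel])
    adj = dmat[sel_c[:-1], sel_c[1:]].copy()
    lam_val = lam if lam is not None else calibrate_lambda(adj)
    return Frameset(frames, traj.elements, align_idx, disp_idx, lam_val, adj)


def calibrate_lambda(adjacent_msd) -> float:
    """λ = ln(10) / ⟨adjacent MSD⟩ (Å⁻²).

    A configuration one inter-frame spacing away from a frame then enters
    the S/Z sums with weight 0.1 relative to the nearest frame, which
    keeps S smooth but localised.  For the frameset spacing of 1.1 Å
    (1.21 Å² MSD) this gives λ ≈ 1.90.
    """
    if isinstance(adjacent_msd, Frameset):
        adjacent_msd = adjacent_msd.adjacent_msd
    mean = float(np.mean(np.asarray(adjacent_msd, dtype=float)))
    if mean <= 0:
        raise ValueError("mean adjacent spacing must be positive")
    return math.log(10.0) / mean


def evaluate_path_cv(config, frameset: Frameset) -> PathCVValue:
    """Evaluate S, Z and their analytic gradients for one configuration.

    Sums are evaluated in log-sum-exp form, so large λ·D never underflows
    to an error.
    """
    coords = (
        config.coordinates if isinstance(config, Configuration) else np.asarray(config)
    )
    if coords.shape[0] != frameset.coords.shape[1]:
        raise ValueError("configuration/frameset topology mismatch")
    coords = np.ascontiguousarray(coords, dtype=float)
    ds_dx = np.zeros_like(coords)
    dz_dx = np.zeros_like(coords)
    s, z = K.pathcv_eval(
        coords,
        frameset.coords,
        frameset.align_selection,
        frameset.displace_selection,
        frameset.lam,
        ds_dx,
        dz_dx,
    )
    return PathCVValue(float(s), float(z), ds_dx, dz_dx)


def evaluate_path_cv_batch(
    coords: np.ndarray, frameset: Frameset, block: int = 20000
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised S, Z for a stack of frames (F, N, 3); no gradients."""
    coords = np.asarray(coords, dtype=float)
    f_tot = coords.shape[0]
    p_tot = frameset.P
    ai = frameset.align_selection
    di = frameset.displace_selection
    s_out = np.empty(f_tot)
    z_out = np.empty(f_tot)
    ref_a = frameset.coords[:, ai]  # (P, na, 3)
    ref_d = frameset.coords[:, di]
    for lo in range(0, f_tot, block):
        ch = coords[lo : lo + block]
        b = ch.shape[0]
        mob_a = np.broadcast_to(ch[:, None, ai], (b, p_tot, len(ai), 3))
        ref_ab = np.broadcast_to(ref_a[None], (b, p_tot, len(ai), 3))
        rot, cm, cr, _ = _kearsley_batch(mob_a, ref_ab)
        mob_d = ch[:, None, di] - cm[..., None, :]
        moved = np.einsum("bpcd,bpkd->bpkc", rot, mob_d) + cr[..., None, :]
        dmat = np.mean(np.sum((moved - ref_d[None]) ** 2, axis=3), axis=2)  # (b, P)
        lam = frameset.lam
        dmin = dmat.min(axis=1, keepdims=True)
        w = np.exp(-lam * (dmat - dmin))
        wsum = w.sum(axis=1)
        s_out[lo : lo + b] = (w * np.arange(1, p_tot + 1)).sum(axis=1) / wsum
        z_out[lo : lo + b] = dmin[:, 0] - np.log(wsum) / lam
    return s_out, z_out


class PathCV:
    """Adapter exposing a frameset to the metadynamics engine."""

    mode = 1

    def __init__(self, frameset: Frameset):
        self.frameset = frameset

    def __call__(self, coords: np.ndarray) -> PathCVValue:
        return evaluate_path_cv(coords, self.frameset)
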