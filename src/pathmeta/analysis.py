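"""Free-energy-surface and trajectory analyses.

Covers the post-processing layer of the sampling pipeline: watershed
basin detection with shallow-basin merging and minimum-to-minimum ΔG,
lowest-saddle (minimax) barriers, smooth water-coordination counts with
the rational switching function, hydration maps along a pocket axis as a
function of the path progression S, geometry monitors (distances,
dihedrals, RMSD/RMSF), a catalytic-competence predicate, and
single-linkage conformational clustering.
"""

from __future__ import annotations

import heapq
import math
import string
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import Configuration, Trajectory
from .metadynamics import FreeEnergySurface
from .pathcv import _kearsley_batch, superpose

__all__ = [
    "Basin",
    "SwitchingParams",
    "SegmentAxis",
    "find_basins",
    "basin_delta_g",
    "barrier_height",
    "coordination_count",
    "hydration_map",
    "monitor_distance",
    "monitor_dihedral",
    "rmsd_rmsf",
    "is_catalytically_competent",
    "cluster_single_linkage",
]


# ---------------------------------------------------------------------------
# Basin analysis
# ---------------------------------------------------------------------------


@dataclass
class Basin:
    """A local free-energy minimum and the grid cells draining into it."""

    label: str
    minimum: tuple[float, float]  # (s, z) of the minimum cell
    depth: float  # F at the minimum, relative to the global minimum
    cells: np.ndarray  # (k, 2) integer grid indices
    min_index: tuple[int, int] = (0, 0)


def _steepest_descent_labels(values: np.ndarray) -> np.ndarray:
    """Assign each grid cell to a local minimum by 8-neighbour descent."""
    ns, nz = values.shape
    labels = -np.ones((ns, nz), dtype=int)
    order = np.dstack(np.unravel_index(np.argsort(values, axis=None), values.shape))[0]
    nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    n_min = 0
    for i, j in order:
        best = values[i, j]
        target = None
        for di, dj in nbrs:
            a, b = i + di, j + dj
            if 0 <= a < ns and 0 <= b < nz and values[a, b] < best:
                best = values[a, b]
                target = (a, b)
        if target is None:
            labels[i, j] = n_min
            n_min += 1
        else:
            labels[i, j] = labels[target]
    return labels


def _basin_names(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for k in range(n):
        name = ""
        k2 = k
        while True:
            name = letters[k2 % 26] + name
            k2 = k2 // 26 - 1
            if k2 < 0:
                break
        out.append(name)
    return out


def find_basins(fes: FreeEnergySurface, min_depth: float = 1.0) -> list[Basin]:
    """Watershed basins of the surface, shallow ones merged away.

    Basins whose prominence (lowest saddle to a deeper neighbouring basin
    minus the basin minimum) is below ``min_depth`` are absorbed into that
    neighbour; the default threshold of 1 kcal mol⁻¹ matches the isoline
    spacing used to render the surface, so surviving basins are the ones
    visible on the plot.  Returned sorted deepest-first and labelled
    A, B, C, …
    """
    values = fes.values
    if values.size == 0:
        return []
    if np.ptp(values) < 1e-12:
        return []
    labels = _steepest_descent_labels(values)
    ns, nz = values.shape

    def saddles(lab):
        """Lowest pass value between each pair of adjacent basins."""
        out: dict[tuple[int, int], float] = {}
        for i in range(ns):
            for j in range(nz):
                a = lab[i, j]
                for di, dj in ((1, 0), (0, 1), (1, 1), (1, -1)):
                    x, y = i + di, j + dj
                    if 0 <= x < ns and 0 <= y < nz and lab[x, y] != a:
                        b = lab[x, y]
                        key = (min(a, b), max(a, b))
                        v = max(values[i, j], values[x, y])
                        if key not in out or v < out[key]:
                            out[key] = v
        return out

    while True:
        ids = np.unique(labels)
        if len(ids) <= 1:
            break
        mins = {k: values[labels == k].min() for k in ids}
        passes = saddles(labels)
        # merge the least prominent shallow basin into its spill neighbour
        best = None
        for (a, b), v in passes.items():
            for shallow, other in ((a, b), (b, a)):
                if mins[shallow] < mins[other]:
                    continue  # only merge the shallower of the pair
                prom = v - mins[shallow]
                if prom < min_depth and (best is None or prom < best[0]):
                    best = (prom, shallow, other)
        if best is None:
            break
        _, shallow, other = best
        labels[labels == shallow] = other

    ids = np.unique(labels)
    basins = []
    for k in ids:
        cells = np.argwhere(labels == k)
        vals = values[cells[:, 0], cells[:, 1]]
        imin = cells[int(np.argmin(vals))]
        basins.append(
            (
                float(values[imin[0], imin[1]]),
                (int(imin[0]), int(imin[1])),
                cells,
            )
        )
    basins.sort(key=lambda b: b[0])
    names = _basin_names(len(basins))
    out = []
    for name, (fmin, (i, j), cells) in zip(names, basins):
        out.append(
            Basin(
                label=name,
                minimum=(float(fes.s_grid[i]), float(fes.z_grid[j])),
                depth=fmin - float(values.min()),
                cells=cells,
                min_index=(i, j),
            )
        )
    return out


def _resolve_basin(basins: list[Basin], which) -> Basin:
    if isinstance(which, Basin):
        return which
    for b in basins:
        if b.label == which:
            return b
    raise KeyError(f"unknown basin label {which!r}")


def basin_delta_g(fes: FreeEnergySurface, basin_a: Basin, basin_b: Basin) -> float:
    """Minimum-to-minimum free-energy difference F(b) − F(a); positive when
    basin a is the deeper (more stable) one."""
    fa = fes.values[basin_a.min_index]
    fb = fes.values[basin_b.min_index]
    return float(fb - fa)


def barrier_height(fes: FreeEnergySurface, basin_a: Basin, basin_b: Basin) -> float:
    """Lowest-saddle (minimax-path) barrier from basin a to basin b.

    Dijkstra-style search on the grid (4-connectivity) where the cost of
    a path is the maximum cell value along it; the barrier is that
    minimax value minus F at the minimum of basin a.
    """
    values = fes.values
    ns, nz = values.shape
    start = basin_a.min_index
    goal = basin_b.min_index
    best = np.full((ns, nz), np.inf)
    h0 = max(values[start], values[start])
    heap = [(values[start], start)]
    best[start] = values[start]
    while heap:
        cost, (i, j) = heapq.heappop(heap)
        if (i, j) == goal:
            return float(cost - values[basin_a.min_index])
        if cost > best[i, j]:
            continue
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < ns and 0 <= b < nz:
                c = max(cost, values[a, b])
                if c < best[a, b]:
                    best[a, b] = c
                    heapq.heappush(heap, (c, (a, b)))
    raise ValueError("basins are not connected on the grid")


# ---------------------------------------------------------------------------
# Hydration / coordination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function (1−(r/r0)ⁿ)/(1−(r/r0)ᵐ).

    Defaults r0 = 3.5 Å, n = 6, m = 16: ≈1 well inside r0, 0 beyond, with
    the removable singularity at r = r0 worth n/m.
    """

    r0: float = 3.5
    n: int = 6
    m: int = 16

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.n <= 0 or self.n % 2 or self.m <= self.n or self.m % 2:
            raise ValueError("need even integers 0 < n < m")


@dataclass
class SegmentAxis:
    """Evenly spaced probe points along a segment (pocket major axis)."""

    start: np.ndarray
    end: np.ndarray
    n_slices: int = 10

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if self.n_slices < 1:
            raise ValueError("need at least one slice")

    @property
    def fractions(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_slices + 1)

    @property
    def points(self) -> np.ndarray:
        """n_slices + 1 points at fractions 0.0, …, 1.0 of the segment."""
        f = self.fractions[:, None]
        return (1.0 - f) * self.start + f * self.end


def coordination_count(point, waters, params: SwitchingParams = SwitchingParams()):
    """Smooth number of waters coordinating a probe point.

    Evaluated through the equivalent polynomial-ratio form
    Σ_{k<n} xᵏ / Σ_{k<m} xᵏ with x = r/r0, which is exactly the rational
    switching function with its r = r0 singularity removed (value n/m).
    """
    waters = np.atleast_2d(np.asarray(waters, dtype=float))
    if waters.size == 0:
        return 0.0
    r = np.linalg.norm(waters - np.asarray(point, dtype=float), axis=1)
    x = r / params.r0
    num = np.zeros_like(x)
    den = np.zeros_like(x)
    xk = np.ones_like(x)
    for k in range(params.m):
        if k < params.n:
            num += xk
        den += xk
        xk = xk * x
    return float(np.sum(num / den))


def hydration_map(
    traj: Trajectory,
    s_series,
    axis: SegmentAxis,
    params: SwitchingParams = SwitchingParams(),
    s_bin: float = 0.5,
):
    """Mean water coordination per (axis point, S-bin).

    For every frame the coordination count of the ``water_O`` group is
    evaluated at each axis point; frames are pooled into S-bins of width
    ``s_bin`` (Z is marginalised — no filtering on the distance from the
    path).  Returns (grid of shape (n_points, n_bins), bin_edges).
    """
    if "water_O" not in traj.groups:
        raise KeyError("trajectory has no water_O group")
    s_series = np.asarray(s_series, dtype=float)
    if len(s_series) != len(traj):
        raise ValueError("s_series must align with trajectory frames")
    waters = traj.groups["water_O"]
    pts = axis.points
    lo = math.floor(s_series.min() / s_bin) * s_bin
    hi = math.ceil(s_series.max() / s_bin) * s_bin
    edges = np.arange(lo, hi + s_bin / 2, s_bin)
    if len(edges) < 2:
        edges = np.array([lo, lo + s_bin])
    which = np.clip(np.digitize(s_series, edges) - 1, 0, len(edges) - 2)
    grid = np.zeros((len(pts), len(edges) - 1))
    counts = np.zeros(len(edges) - 1)
    for f in range(len(traj)):
        w = traj.coords[f][waters]
        b = which[f]
        counts[b] += 1
        for p, pt in enumerate(pts):
            grid[p, b] += coordination_count(pt, w, params) if len(w) else 0.0
    with np.errstate(invalid="ignore"):
        grid = np.where(counts > 0, grid / np.maximum(counts, 1), np.nan)
    return grid, edges


# ---------------------------------------------------------------------------
# Geometry monitors
# ---------------------------------------------------------------------------


def monitor_distance(traj: Trajectory, sel_a, sel_b, mode: str = "centroid") -> np.ndarray:
    """Per-frame distance (Å) between two selections.

    ``atom`` mode requires singleton selections; ``centroid`` uses the
    geometric centres.
    """
    tmp = Configuration(traj.coords[0], traj.elements, traj.names, traj.groups)
    ia = tmp.select(sel_a)
    ib = tmp.select(sel_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("selections must be non-empty")
    if mode == "atom":
        if len(ia) != 1 or len(ib) != 1:
            raise ValueError("atom mode requires singleton selections")
        pa = traj.coords[:, ia[0]]
        pb = traj.coords[:, ib[0]]
    elif mode == "centroid":
        pa = traj.coords[:, ia].mean(axis=1)
        pb = traj.coords[:, ib].mean(axis=1)
    else:
        raise ValueError("mode must be 'atom' or 'centroid'")
    return np.linalg.norm(pa - pb, axis=1)


def monitor_dihedral(traj: Trajectory, atoms) -> np.ndarray:
    """Signed dihedral (degrees, (−180, 180]) over four atoms, per frame."""
    atoms = list(atoms)
    if len(atoms) != 4 or len(set(atoms)) != 4:
        raise ValueError("need four distinct atoms")
    p = traj.coords[:, atoms]  # (F, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=1) < 1e-10) or np.any(
        np.linalg.norm(n2, axis=1) < 1e-10
    ):
        raise ValueError("collinear atoms: dihedral undefined in some frame")
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def rmsd_rmsf(traj: Trajectory, align_selection, measure_selection):
    """Per-frame RMSD to frame 0 and per-atom RMSF after alignment.

    Every frame is least-squares fitted to frame 0 on the alignment
    selection; RMSD is over the measure selection, RMSF is the per-atom
    root-mean-square deviation from the time-mean aligned structure.
    """
    tmp = Configuration(traj.coords[0], traj.elements, traj.names, traj.groups)
    ai = tmp.select(align_selection)
    mi = tmp.select(measure_selection)
    ref = traj.coords[0]
    mob_a = traj.coords[:, ai]
    ref_a = np.broadcast_to(ref[ai], mob_a.shape)
    rot, cm, cr, _ = _kearsley_batch(mob_a, ref_a)
    moved = np.einsum(
        "fcd,fkd->fkc", rot, traj.coords[:, mi] - cm[:, None, :]
    ) + cr[:, None, :]
    rmsd = np.sqrt(np.mean(np.sum((moved - ref[mi]) ** 2, axis=2), axis=1))
    mean_structure = moved.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((moved - mean_structure) ** 2, axis=2), axis=0))
    return rmsd, rmsf


DEFAULT_CUTOFFS = {"hydride": 4.5, "hbond": 3.5}


def is_catalytically_competent(
    frame: Configuration,
    roles: dict,
    hydride_cutoff: float = DEFAULT_CUTOFFS["hydride"],
    hbond_cutoff: float = DEFAULT_CUTOFFS["hbond"],
):
    """Distance-based predicate for a reaction-ready ligand pose.

    ``roles`` maps the five participating atoms to indices:
    ``hydride_donor`` / ``hydride_acceptor`` (the hydride-transfer pair),
    ``keto_oxygen`` and the two stabilising hydroxyl oxygens
    ``tyr_oxygen`` / ``ser_oxygen``.  Competence requires the hydride
    distance within ``hydride_cutoff`` AND both keto–hydroxyl hydrogen
    bonds within ``hbond_cutoff``.  Returns (bool, per-criterion
    distances dict).
    """
    required = ("hydride_donor", "hydride_acceptor", "keto_oxygen", "tyr_oxygen", "ser_oxygen")
    for key in required:
        if key not in roles:
            raise KeyError(f"missing role {key!r}")
    x = frame.coordinates

    def dist(i, j):
        return float(np.linalg.norm(x[i] - x[j]))

    d = {
        "hydride": dist(roles["hydride_donor"], roles["hydride_acceptor"]),
        "hbond_tyr": dist(roles["keto_oxygen"], roles["tyr_oxygen"]),
        "hbond_ser": dist(roles["keto_oxygen"], roles["ser_oxygen"]),
    }
    ok = (
        d["hydride"] <= hydride_cutoff
        and d["hbond_tyr"] <= hbond_cutoff
        and d["hbond_ser"] <= hbond_cutoff
    )
    return ok, d


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_single_linkage(
    configs, align_selection, measure_selection, cutoff: float = 0.7
) -> np.ndarray:
    """Single-linkage clustering on pairwise fitted RMSD.

    Pairs closer than ``cutoff`` (Å) are linked; clusters are the
    connected components of the resulting graph, labelled 0, 1, … by
    decreasing size (ties: lowest member index first).
    """
    if len(configs) == 0:
        raise ValueError("need at least one configuration")
    if isinstance(configs, Trajectory):
        coords = configs.coords
        tmp = Configuration(coords[0], configs.elements, configs.names, configs.groups)
    else:
        coords = np.stack([c.coordinates for c in configs])
        tmp = configs[0]
    ai = tmp.select(align_selection)
    mi = tmp.select(measure_selection)
    n = len(coords)
    if n == 1:
        return np.zeros(1, dtype=int)
    ii, jj = np.triu_indices(n, k=1)
    rot, cm, cr, _ = _kearsley_batch(coords[ii][:, ai], coords[jj][:, ai])
    moved = np.einsum("bcd,bkd->bkc", rot, coords[ii][:, mi] - cm[:, None, :])
    moved += cr[:, None, :]
    rmsd = np.sqrt(np.mean(np.sum((moved - coords[jj][:, mi]) ** 2, axis=2), axis=1))
    link = rmsd <= cutoff
    graph = coo_matrix(
        (np.ones(link.sum()), (ii[link], jj[link])), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)
    sizes = np.bincount(comp)
    first = np.array([np.argmax(comp == k) for k in range(n_comp)])
    order = sorted(range(n_comp), key=lambda k: (-sizes[k], first[k]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in comp], dtype=int)
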