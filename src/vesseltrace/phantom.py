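"""Synthetic cleared-brain vascular phantoms with known ground truth.

Real whole-brain stacks come with no voxel-level truth, so quantitative
validation of a segmentation/tracing chain needs phantoms: branching
capillary-scale tubes (radii of a few µm) grown by a seeded random walk to a
target vascular density (mm of centerline per mm³ of tissue), rasterized on
an anisotropic light-sheet voxel grid, and rendered under either of the two
staining regimes found in practice:

* ``lumen`` — the fluorophore fills the whole vessel interior
  (gel-albumin conjugates), giving solid bright tubes;
* ``wall``  — only a thin endothelial band is labelled (lectin-type
  markers), giving hollow outlines that fade quickly with depth.

Rendering applies an exponential depth attenuation along z, an isotropic
Gaussian PSF, and mixed Poisson–Gaussian noise.  Every phantom carries its
binary ground-truth mask and the exact centerline graph it was grown from.

Axis convention throughout: arrays are depth-major ``(z, y, x)``; voxel
``(i, j, k)`` has its center at ``((i+0.5)·vz, (j+0.5)·vy, (k+0.5)·vx)`` µm.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .graph import CenterlineGraph, Edge, Node

__all__ = [
    "PhantomSpec",
    "StainSpec",
    "VesselSegment",
    "VesselTree",
    "Phantom",
    "generate_tree",
    "tree_to_graph",
    "rasterize",
    "render",
    "make_phantom",
]


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling of a synthetic vascular volume.

    Parameters
    ----------
    domain_um:
        Axis-aligned box extents in µm, ``(z, y, x)``.
    voxel_um:
        Voxel pitch in µm, ``(z, y, x)``.  Default (2.0, 0.65, 0.65) is the
        light-sheet acquisition geometry (2 µm z-step, 0.65 µm in plane).
    density_mm_per_mm3:
        Target vascular density — centerline length per tissue volume.
        Default 450 mm/mm³, in the range reported for mouse hippocampus.
    radius_um:
        (min, max) vessel radius; one radius per segment, drawn uniformly.
    branch_prob_per_um:
        Bernoulli branching probability per µm of grown centerline.
    n_roots:
        Number of independent seed vessels.
    seed:
        Seed for all phantom randomness (growth and rendering noise).
    step_um:
        Elongation step of the random-walk growth.
    """

    domain_um: tuple[float, float, float]
    voxel_um: tuple[float, float, float] = (2.0, 0.65, 0.65)
    density_mm_per_mm3: float = 450.0
    radius_um: tuple[float, float] = (2.0, 5.0)
    branch_prob_per_um: float = 0.02
    n_roots: int = 8
    seed: int = 0
    step_um: float = 2.0

    def __post_init__(self) -> None:
        if len(self.domain_um) != 3 or any(d <= 0 for d in self.domain_um):
            raise ValueError("domain_um must be three positive extents")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be positive")
        if self.density_mm_per_mm3 <= 0:
            raise ValueError("target density must be positive")
        rmin, rmax = self.radius_um
        if not (0 < rmin <= rmax):
            raise ValueError("radius range must satisfy 0 < min <= max")
        if self.n_roots < 1:
            raise ValueError("need at least one seed root")
        if self.step_um <= 0:
            raise ValueError("growth step must be positive")
        if self.target_length_um < 10 * self.step_um:
            raise ValueError(
                "domain too small: target centerline length is below 10 growth "
                "steps, so the realized density cannot track the target"
            )

    @classmethod
    def from_shape(
        cls,
        shape: tuple[int, int, int],
        voxel_um: tuple[float, float, float] = (2.0, 0.65, 0.65),
        **kwargs,
    ) -> "PhantomSpec":
        """Spec whose domain is ``shape`` voxels at the given pitch."""
        domain = tuple(s * v for s, v in zip(shape, voxel_um))
        return cls(domain_um=domain, voxel_um=voxel_um, **kwargs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(d / v)) for d, v in zip(self.domain_um, self.voxel_um))

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.domain_um))

    @property
    def target_length_um(self) -> float:
        # density [mm/mm³] = 1e-6 µm of length per µm³ of volume
        return self.density_mm_per_mm3 * self.volume_um3 * 1e-6


@dataclass(frozen=True)
class StainSpec:
    """Staining contrast and image-degradation model.

    ``lumen`` mode fills the whole vessel cross-section at foreground
    intensity; ``wall`` mode labels only a band of ``wall_thickness_um``
    centered on the vessel surface.  The noise-free value at voxel *v* is

        bg + (fg − bg) · M(v) · exp(−z_v / λ)

    followed by Gaussian PSF blur, optional Poisson shot noise (scaled by
    ``poisson_gain``; 0 disables), and additive Gaussian read noise.
    """

    mode: str = "lumen"  # lumen | wall
    wall_thickness_um: float = 1.0
    foreground: float = 200.0
    background: float = 20.0
    attenuation_um: float = 1500.0  # exponential decay length λ along z; inf = none
    psf_sigma_um: float = 1.0
    noise_sd: float = 10.0
    poisson_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("lumen", "wall"):
            raise ValueError(f"unknown stain mode {self.mode!r}")
        if not self.foreground > self.background >= 0:
            raise ValueError("need foreground > background >= 0")
        if self.attenuation_um <= 0:
            raise ValueError("attenuation decay length must be positive")
        if self.mode == "wall" and self.wall_thickness_um <= 0:
            raise ValueError("wall thickness must be positive in wall mode")
        if self.psf_sigma_um < 0 or self.noise_sd < 0 or self.poisson_gain < 0:
            raise ValueError("psf sigma, noise sd and poisson gain must be >= 0")


# --------------------------------------------------------------------------
# Vessel tree growth
# --------------------------------------------------------------------------


@dataclass
class VesselSegment:
    """One unbranched vessel run: an ordered polyline with constant radius."""

    points_um: np.ndarray  # (n, 3) (z, y, x) µm
    radius_um: float
    parent: int | None = None  # index of parent segment
    parent_point: int | None = None  # attachment index into parent's polyline

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.points_um, axis=0), axis=1).sum())


@dataclass
class VesselTree:
    segments: list[VesselSegment]
    domain_um: tuple[float, float, float]

    @property
    def total_length_um(self) -> float:
        return float(sum(s.length_um for s in self.segments))

    def validate(self) -> None:
        dom = np.asarray(self.domain_um)
        for i, seg in enumerate(self.segments):
            if seg.radius_um <= 0:
                raise ValueError("all radii must be positive")
            if seg.points_um.shape[0] < 2:
                raise ValueError("each polyline needs at least 2 points")
            if np.any(seg.points_um < 0) or np.any(seg.points_um > dom):
                raise ValueError("tree points outside domain")
            if seg.parent is not None and seg.parent >= i:
                raise ValueError("parent indices must precede children (forest)")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-9:
            return v / n


_MAX_ACTIVE_TIPS = 64
_DIRECTION_JITTER = 0.15  # sd of per-step direction perturbation (tortuosity)
_CLEARANCE_UM = 2.0  # minimum surface-to-surface gap between distinct vessels
_STEP_ATTEMPTS = 8


class _CollisionGrid:
    """Uniform-grid spatial hash over centerline samples for exclusion tests.

    Real capillaries never interpenetrate: distinct vessels keep their
    surfaces apart.  Each grown point is stored with its radius, segment id
    and index along that segment; a proposed point collides if any sample
    from another vessel is closer than the sum of radii plus a clearance
    gap.  A parent and its child are exempt from each other only within a
    few steps of the attachment point, where their tubes genuinely share
    space at the bifurcation; farther away they exclude each other like any
    other pair, so a branch cannot run hidden inside its parent.
    """

    def __init__(self, cell_um: float):
        self.cell = cell_um
        self.cells: dict[tuple[int, int, int], list[int]] = {}
        self.points: list[np.ndarray] = []
        self.radii: list[float] = []
        self.seg_ids: list[int] = []
        self.pt_idx: list[int] = []

    def add(self, p: np.ndarray, r: float, seg: int, idx: int) -> None:
        i = len(self.points)
        self.points.append(np.asarray(p, dtype=float))
        self.radii.append(r)
        self.seg_ids.append(seg)
        self.pt_idx.append(idx)
        key = tuple(int(c // self.cell) for c in p)
        self.cells.setdefault(key, []).append(i)

    def collides(self, p: np.ndarray, r: float, is_exempt) -> bool:
        kz, ky, kx = (int(c // self.cell) for c in p)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for i in self.cells.get((kz + dz, ky + dy, kx + dx), ()):
                        if is_exempt(self.seg_ids[i], self.pt_idx[i]):
                            continue
                        lim = r + self.radii[i] + _CLEARANCE_UM
                        if np.linalg.norm(p - self.points[i]) < lim:
                            return True
        return False


def generate_tree(spec: PhantomSpec, rng: np.random.Generator | None = None) -> VesselTree:
    """Grow a branching capillary network to the spec's target density.

    Iterative random-walk elongation: each active tip advances ``step_um``
    per iteration with a small direction perturbation, reflects off the
    domain walls, and spawns a child branch with probability
    ``branch_prob_per_um · step_um``.  Distinct vessels exclude each other
    (surfaces never closer than a small clearance), as in real vascular
    beds; a tip that cannot advance without collision terminates and a new
    seed vessel is planted elsewhere.  Growth stops as soon as the total
    centerline length reaches ``density · volume``, so the realized density
    matches the target to within one step.

    Deterministic given ``spec.seed`` (or an explicitly passed generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rmin, rmax = spec.radius_um
    margin = rmax
    lo = np.full(3, margin, dtype=float)
    hi = np.asarray(spec.domain_um, dtype=float) - margin
    if np.any(hi <= lo):
        raise ValueError(
            "unreachable density: domain too small for the radius range "
            f"(domain {spec.domain_um} µm, max radius {rmax} µm)"
        )

    h = spec.step_um
    target = spec.target_length_um
    segments: list[dict] = []
    tips: list[dict] = []  # {"seg": idx, "dir": unit vec}
    grid = _CollisionGrid(cell_um=2.0 * rmax + _CLEARANCE_UM + h)
    # attachment exemption window: the bifurcation region shared by parent
    # and child, a couple of tube diameters around the attachment point
    win = int(math.ceil((2.0 * rmax + _CLEARANCE_UM) / h)) + 1
    children: dict[int, list[int]] = {}

    def _new_segment(start: np.ndarray, direction: np.ndarray,
                     parent: int | None, parent_point: int | None) -> int:
        idx = len(segments)
        segments.append(
            {
                "points": [np.array(start, dtype=float)],
                "radius": float(rng.uniform(rmin, rmax)),
                "parent": parent,
                "parent_point": parent_point,
            }
        )
        tips.append({"seg": idx, "dir": np.array(direction, dtype=float)})
        children[idx] = []
        if parent is not None:
            children[parent].append(idx)
        return idx

    def _exemption(seg_idx: int, at_point: int):
        seg = segments[seg_idx]
        par = seg["parent"]

        def is_exempt(other_seg: int, other_idx: int) -> bool:
            if other_seg == seg_idx:
                return True
            if other_seg == par and at_point <= win:
                return abs(other_idx - seg["parent_point"]) <= win
            if other_seg in children[seg_idx]:
                ap = segments[other_seg]["parent_point"]
                return other_idx <= win and abs(at_point - ap) <= win
            return False

        return is_exempt

    def _spawn_root(z_band: tuple[float, float] | None = None) -> bool:
        for _ in range(50):
            p = rng.uniform(lo, hi)
            if z_band is not None:
                p[0] = rng.uniform(*z_band)
            if not grid.collides(p, rmax, lambda s, i: False):
                seg = _new_segment(p, _random_unit(rng), None, None)
                grid.add(p, segments[seg]["radius"], seg, 0)
                return True
        return False

    # stratify the seed vessels along depth so the whole stack is
    # vascularized (real cortical tissue has no avascular slabs)
    z_edges = np.linspace(lo[0], hi[0], spec.n_roots + 1)
    for i in range(spec.n_roots):
        _spawn_root(z_band=(z_edges[i], z_edges[i + 1]))
    if not tips:
        raise RuntimeError("unreachable density: could not place any seed vessel")

    total = 0.0
    max_steps = int(20 * target / h) + 100_000
    steps = 0
    failed_spawns = 0
    p_branch = min(1.0, spec.branch_prob_per_um * h)
    while total < target:
        if not tips:
            if not _spawn_root():
                failed_spawns += 1
                if failed_spawns > 20:
                    raise RuntimeError(
                        "unreachable density: no room left for further vessels"
                    )
                continue
        for tip in list(tips):
            seg_idx = tip["seg"]
            seg = segments[seg_idx]
            pos = seg["points"][-1]
            r = seg["radius"]
            placed = False
            jitter = _DIRECTION_JITTER
            for _attempt in range(_STEP_ATTEMPTS):
                d = tip["dir"] + jitter * rng.normal(size=3)
                n = np.linalg.norm(d)
                d = d / n if n > 1e-9 else _random_unit(rng)
                cand = pos + h * d
                for ax in range(3):  # reflect off walls
                    if cand[ax] < lo[ax] or cand[ax] > hi[ax]:
                        d[ax] = -d[ax]
                cand = np.clip(pos + h * d, lo, hi)
                if not grid.collides(cand, r, _exemption(seg_idx, len(seg["points"]))):
                    tip["dir"] = d
                    placed = True
                    break
                jitter *= 2.0  # search wider when blocked
            if not placed:
                tips.remove(tip)  # tip walled in; terminate it
                continue
            new = cand
            seg["points"].append(new)
            grid.add(new, r, seg_idx, len(seg["points"]) - 1)
            total += float(np.linalg.norm(new - pos))
            if total >= target:
                break
            if len(tips) < _MAX_ACTIVE_TIPS and rng.random() < p_branch:
                child_dir = tip["dir"] + rng.normal(size=3)
                nn = np.linalg.norm(child_dir)
                child_dir = child_dir / nn if nn > 1e-9 else _random_unit(rng)
                child = _new_segment(new, child_dir, seg_idx, len(seg["points"]) - 1)
                grid.add(new, segments[child]["radius"], child, 0)
            steps += 1
            if steps > max_steps:
                raise RuntimeError(
                    "unreachable density: growth did not attain the target length"
                )
        else:
            continue
        break

    out: list[VesselSegment] = []
    keep = {}
    for i, s in enumerate(segments):
        if len(s["points"]) < 2:  # child spawned just as growth ended
            continue
        keep[i] = len(out)
        parent = s["parent"]
        out.append(
            VesselSegment(
                points_um=np.asarray(s["points"]),
                radius_um=s["radius"],
                parent=None if parent is None else keep[parent],
                parent_point=s["parent_point"],
            )
        )
    tree = VesselTree(out, tuple(spec.domain_um))
    tree.validate()
    return tree


def tree_to_graph(tree: VesselTree) -> CenterlineGraph:
    """Exact centerline graph of a grown tree (no skeletonization involved).

    Nodes sit at segment ends and branch attachment points; edges are the
    sub-polylines between consecutive nodes along each segment and carry the
    segment radius at every point.
    """
    # cut indices per segment: ends plus every child attachment
    cuts: list[set[int]] = [set([0, s.points_um.shape[0] - 1]) for s in tree.segments]
    for s in tree.segments:
        if s.parent is not None:
            cuts[s.parent].add(int(s.parent_point))

    node_ids: dict[tuple[int, int], int] = {}
    graph = CenterlineGraph()

    def _node(seg_idx: int, pt_idx: int) -> int:
        seg = tree.segments[seg_idx]
        # a child's first point is the parent's attachment point: same node
        if pt_idx == 0 and seg.parent is not None:
            return _node(seg.parent, int(seg.parent_point))
        key = (seg_idx, pt_idx)
        if key not in node_ids:
            nid = len(graph.nodes)
            node_ids[key] = nid
            graph.nodes.append(Node(nid, seg.points_um[pt_idx].copy()))
        return node_ids[key]

    for si, seg in enumerate(tree.segments):
        order = sorted(cuts[si])
        for a, b in zip(order[:-1], order[1:]):
            u, v = _node(si, a), _node(si, b)
            poly = seg.points_um[a : b + 1]
            radii = np.full(poly.shape[0], seg.radius_um)
            graph.edges.append(Edge(u, v, poly, radii, 2.0 * seg.radius_um))
    graph.simplify()
    return graph


# --------------------------------------------------------------------------
# Rasterization and rendering
# --------------------------------------------------------------------------


def _sample_centerline(tree: VesselTree, ds_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample all polylines at ~ds_um spacing; returns (points, radii)."""
    pts, rads = [], []
    for seg in tree.segments:
        d = np.linalg.norm(np.diff(seg.points_um, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(d)])
        n = max(2, int(math.ceil(t[-1] / ds_um)) + 1)
        ti = np.linspace(0.0, t[-1], n)
        res = np.column_stack([np.interp(ti, t, seg.points_um[:, ax]) for ax in range(3)])
        pts.append(res)
        rads.append(np.full(n, seg.radius_um))
    if not pts:
        return np.empty((0, 3)), np.empty((0,))
    return np.vstack(pts), np.concatenate(rads)


def rasterize(
    tree: VesselTree,
    spec: PhantomSpec,
    mode: str = "lumen",
    wall_thickness_um: float = 1.0,
) -> np.ndarray:
    """Voxelize a tree on the spec's grid.

    A voxel is foreground iff the distance from its center to the nearest
    centerline point satisfies, for that point's radius *r*:

    * ``lumen`` mode: distance ≤ r;
    * ``wall`` mode:  r − t/2 ≤ distance ≤ r + t/2 (band of thickness *t*).

    Distances are exact against the polylines resampled at half the minimum
    voxel pitch, evaluated with a k-d tree.
    """
    if mode not in ("lumen", "wall"):
        raise ValueError(f"unknown rasterization mode {mode!r}")
    shape = spec.shape
    mask = np.zeros(shape, dtype=bool)
    pts, rads = _sample_centerline(tree, ds_um=min(spec.voxel_um) / 2.0)
    if pts.shape[0] == 0:
        warnings.warn("empty vessel tree: rasterized mask is all background")
        return mask
    kdt = cKDTree(pts)
    vz, vy, vx = spec.voxel_um
    yc = (np.arange(shape[1]) + 0.5) * vy
    xc = (np.arange(shape[2]) + 0.5) * vx
    half_t = wall_thickness_um / 2.0
    # chunk over z to bound the query memory
    chunk = max(1, int(2_000_000 // (shape[1] * shape[2])) or 1)
    for z0 in range(0, shape[0], chunk):
        z1 = min(shape[0], z0 + chunk)
        zc = (np.arange(z0, z1) + 0.5) * vz
        grid = np.stack(np.meshgrid(zc, yc, xc, indexing="ij"), axis=-1).reshape(-1, 3)
        dist, idx = kdt.query(grid, workers=-1)
        r = rads[idx]
        if mode == "lumen":
            sel = dist <= r
        else:
            sel = (dist >= r - half_t) & (dist <= r + half_t)
        mask[z0:z1] = sel.reshape(z1 - z0, shape[1], shape[2])
    return mask


def render(
    mask: np.ndarray,
    stain: StainSpec,
    voxel_um: tuple[float, float, float],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    clip_max: float = 65535.0,
) -> np.ndarray:
    """Turn a binary mask into a noisy microscope-like intensity volume.

    Stages, in physical order: ideal fluorophore distribution with
    exponential depth attenuation → PSF blur → Poisson shot noise (if
    ``poisson_gain`` > 0) → additive Gaussian read noise → clip to the
    output intensity range.  Returns float32.
    """
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (z, y, x)")
    if rng is None:
        rng = np.random.default_rng(seed)
    vz = voxel_um[0]
    z = (np.arange(mask.shape[0]) + 0.5) * vz
    atten = (
        np.ones_like(z)
        if math.isinf(stain.attenuation_um)
        else np.exp(-z / stain.attenuation_um)
    )
    img = stain.background + (stain.foreground - stain.background) * (
        mask.astype(np.float32) * atten[:, None, None].astype(np.float32)
    )
    if stain.psf_sigma_um > 0:
        sigma_vox = [stain.psf_sigma_um / v for v in voxel_um]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if stain.poisson_gain > 0:
        img = rng.poisson(np.maximum(img, 0.0) / stain.poisson_gain).astype(
            np.float32
        ) * stain.poisson_gain
    if stain.noise_sd > 0:
        img = img + rng.normal(0.0, stain.noise_sd, size=img.shape).astype(np.float32)
    return np.clip(img, 0.0, clip_max).astype(np.float32)


# --------------------------------------------------------------------------
# Phantom assembly
# --------------------------------------------------------------------------


@dataclass
class Phantom:
    """A rendered volume with its exact ground truth."""

    intensity: np.ndarray
    mask: np.ndarray
    graph: CenterlineGraph
    tree: VesselTree
    spec: PhantomSpec
    stain: StainSpec

    def __post_init__(self) -> None:
        if self.intensity.shape != self.mask.shape:
            raise ValueError("intensity and mask shapes differ")
        if not self.mask.any():
            raise ValueError("phantom mask has no foreground")
        target = self.spec.target_length_um
        if abs(self.graph.total_length_um - target) > 0.10 * target:
            raise ValueError("ground-truth length off target by more than 10%")

    def save(self, out_dir: str | Path) -> Path:
        from .stackio import StackMeta, write_stack

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = StackMeta(
            shape=self.intensity.shape,
            dtype="uint16",
            voxel_um=tuple(self.spec.voxel_um),
            provenance=[f"vesseltrace phantom seed={self.spec.seed} mode={self.stain.mode}"],
        )
        write_stack(out / "intensity.tif", np.round(self.intensity).astype(np.uint16), meta)
        write_stack(
            out / "ground_truth_mask.tif",
            (self.mask.astype(np.uint8) * 255),
            replace(meta, dtype="uint8"),
        )
        self.graph.save(out / "ground_truth_graph.json")
        (out / "phantom_spec.json").write_text(
            json.dumps(
                {"spec": _spec_dict(self.spec), "stain": self.stain.__dict__},
                indent=1,
                sort_keys=True,
            )
        )
        return out


def _spec_dict(spec: PhantomSpec) -> dict:
    d = dict(spec.__dict__)
    for k in ("domain_um", "voxel_um", "radius_um"):
        d[k] = list(d[k])
    return d


def make_phantom(spec: PhantomSpec, stain: StainSpec | None = None) -> Phantom:
    """Generate tree, mask, ground-truth graph and rendered intensity.

    All randomness derives from ``spec.seed``: the growth and the rendering
    noise use independent streams spawned from it, so lumen- and wall-mode
    phantoms from the same spec share identical geometry.
    """
    if stain is None:
        stain = StainSpec()
    ss = np.random.SeedSequence(spec.seed)
    rng_tree, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    tree = generate_tree(spec, rng=rng_tree)
    mask = rasterize(tree, spec, mode=stain.mode, wall_thickness_um=stain.wall_thickness_um)
    graph = tree_to_graph(tree)
    intensity = render(mask, stain, spec.voxel_um, rng=rng_noise)
    return Phantom(intensity, mask, graph, tree, spec, stain)
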