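"""Image-quality and segmentation-accuracy measures.

Mirrors how segmentation quality is reported for cleared-brain vascular
stacks: SNR (ratio of mean signal ROI to mean background ROI) profiled
every 20 µm of depth, overlap counts between an automatic and a reference
(manual/ground-truth) mask on 40 µm maximum-intensity-projection slabs,
the derived true-positive / false-positive / false-negative percentage
rates with precision P = TP/(TP+FP) and recall R = TP/(TP+FN), and the
perfusion-completeness rule for vessel branches.

Rate denominators are an explicit convention, recorded in every result:
the default puts TP and FN over the reference-positive pixel count (so
tp_rate + fn_rate = 100 by construction) and FP over the auto-positive
count.  Undefined rates (empty denominator) are reported as missing
(``None``), never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DepthROI",
    "ROISet",
    "DepthProfile",
    "OverlapCounts",
    "snr",
    "snr_profile",
    "build_roi_set",
    "mip",
    "overlap_metrics",
    "depthwise_overlap",
    "classify_perfusion",
]


# --------------------------------------------------------------------------
# SNR
# --------------------------------------------------------------------------


@dataclass
class DepthROI:
    """Signal/background ROI pair at a stated depth.

    ROIs are given as voxel index tuples (as returned by ``np.nonzero``) or
    boolean masks over the full volume.
    """

    depth_um: float
    signal: tuple[np.ndarray, ...]
    background: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        self.signal = _as_index(self.signal)
        self.background = _as_index(self.background)
        if self.signal[0].size == 0 or self.background[0].size == 0:
            raise ValueError("signal and background ROIs must be non-empty")
        sig = set(zip(*(a.tolist() for a in self.signal)))
        bgd = set(zip(*(a.tolist() for a in self.background)))
        if sig & bgd:
            raise ValueError("signal and background ROIs must be disjoint")


def _as_index(roi) -> tuple[np.ndarray, ...]:
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        return np.nonzero(roi)
    return tuple(np.asarray(a, dtype=np.intp) for a in roi)


@dataclass
class ROISet:
    rois: list[DepthROI] = field(default_factory=list)


@dataclass
class DepthProfile:
    """A metric sampled at increasing depths (µm)."""

    depths_um: np.ndarray
    values: np.ndarray
    name: str
    n: np.ndarray  # samples per bin

    def __post_init__(self) -> None:
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n = np.asarray(self.n)
        if np.any(np.diff(self.depths_um) <= 0):
            raise ValueError("depths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")


def snr(volume: np.ndarray, signal_roi, background_roi) -> float:
    """SNR as the ratio of ROI mean grey values: mean(signal)/mean(background)."""
    sig = _as_index(signal_roi)
    bgd = _as_index(background_roi)
    if sig[0].size == 0 or bgd[0].size == 0:
        raise ValueError("signal and background ROIs must be non-empty")
    s = float(np.mean(volume[sig]))
    b = float(np.mean(volume[bgd]))
    if b == 0.0:
        raise ValueError("background mean is zero; SNR undefined")
    return s / b


def snr_profile(
    volume: np.ndarray,
    roi_set: ROISet,
    step_um: float = 20.0,
    max_depth_um: float = 500.0,
) -> DepthProfile:
    """One SNR value per depth bin at ``step_um`` spacing from 0 to the max.

    Depths with no matching ROI in the set are omitted with a warning.
    """
    by_depth = {round(r.depth_um, 6): r for r in roi_set.rois}
    depths, values, ns = [], [], []
    for d in np.arange(0.0, max_depth_um + step_um / 2.0, step_um):
        key = round(float(d), 6)
        roi = by_depth.get(key)
        if roi is None:
            warnings.warn(f"no ROI at depth {d:g} µm; bin omitted")
            continue
        depths.append(d)
        values.append(snr(volume, roi.signal, roi.background))
        ns.append(roi.signal[0].size)
    return DepthProfile(np.asarray(depths), np.asarray(values), "snr", np.asarray(ns))


def build_roi_set(
    mask: np.ndarray,
    voxel_z_um: float,
    step_um: float = 20.0,
    max_depth_um: float | None = None,
    background_margin_um: float = 3.0,
    voxel_xy_um: float = 0.65,
) -> ROISet:
    """Derive per-depth signal/background ROIs from a ground-truth mask.

    At each requested depth the signal ROI is the vessel voxels of the
    nearest slice and the background ROI is the slice voxels farther than
    ``background_margin_um`` from any vessel.  Depths whose slice has no
    vessel are skipped.
    """
    nz = mask.shape[0]
    if max_depth_um is None:
        max_depth_um = (nz - 1) * voxel_z_um
    rois = []
    for d in np.arange(0.0, max_depth_um + step_um / 2.0, step_um):
        zi = int(round(d / voxel_z_um))
        if zi >= nz:
            break
        sl = mask[zi]
        if not sl.any() or sl.all():
            continue
        dist = ndimage.distance_transform_edt(~sl, sampling=(voxel_xy_um, voxel_xy_um))
        bg2d = dist > background_margin_um
        if not bg2d.any():
            continue
        sy, sx = np.nonzero(sl)
        by, bx = np.nonzero(bg2d)
        rois.append(
            DepthROI(
                depth_um=float(d),
                signal=(np.full(sy.size, zi, dtype=np.intp), sy, sx),
                background=(np.full(by.size, zi, dtype=np.intp), by, bx),
            )
        )
    return ROISet(rois)


# --------------------------------------------------------------------------
# Projections
# --------------------------------------------------------------------------


def mip(
    volume: np.ndarray,
    z_start_um: float,
    thickness_um: float = 40.0,
    voxel_z_um: float = 2.0,
) -> np.ndarray:
    """Maximum-intensity projection of a slab of slices.

    The slab contains ``round(thickness / voxel_z)`` slices starting at the
    slice nearest ``z_start_um``.
    """
    i0 = int(round(z_start_um / voxel_z_um))
    n = int(round(thickness_um / voxel_z_um))
    if n < 1 or i0 < 0 or i0 >= volume.shape[0]:
        raise ValueError("empty projection slab")
    return volume[i0 : i0 + n].max(axis=0)


# --------------------------------------------------------------------------
# Overlap metrics
# --------------------------------------------------------------------------

_CONVENTIONS = ("default", "reference")


@dataclass(frozen=True)
class OverlapCounts:
    """Pixel overlap between an automatic mask A and a reference mask M.

    TP = |A∩M|, FP = |A∖M|, FN = |M∖A|.  Percentage-rate denominators
    follow ``convention``:

    * ``default``   — tp_rate, fn_rate over |M|; fp_rate over |A|
      (the only convention with tp_rate + fn_rate = 100 by construction);
    * ``reference`` — all three rates over |M|.

    Rates with an empty denominator are ``None`` (missing), never 0.
    """

    tp: int
    fp: int
    fn: int
    convention: str = "default"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.convention not in _CONVENTIONS:
            raise ValueError(f"unknown rate convention {self.convention!r}")

    @property
    def n_auto(self) -> int:
        return self.tp + self.fp

    @property
    def n_reference(self) -> int:
        return self.tp + self.fn

    @property
    def tp_rate(self) -> float | None:
        return 100.0 * self.tp / self.n_reference if self.n_reference else None

    @property
    def fn_rate(self) -> float | None:
        return 100.0 * self.fn / self.n_reference if self.n_reference else None

    @property
    def fp_rate(self) -> float | None:
        den = self.n_reference if self.convention == "reference" else self.n_auto
        return 100.0 * self.fp / den if den else None

    @property
    def precision(self) -> float | None:
        return self.tp / self.n_auto if self.n_auto else None

    @property
    def recall(self) -> float | None:
        # defined via tp_rate so recall == tp_rate / 100 holds exactly
        rate = self.tp_rate
        return rate / 100.0 if rate is not None else None


def overlap_metrics(
    auto_mask: np.ndarray,
    reference_mask: np.ndarray,
    convention: str = "default",
) -> OverlapCounts:
    """Exact TP/FP/FN pixel counts between binary masks of equal shape."""
    a = np.asarray(auto_mask).astype(bool)
    m = np.asarray(reference_mask).astype(bool)
    if a.shape != m.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.count_nonzero(a & m))
    fp = int(np.count_nonzero(a & ~m))
    fn = int(np.count_nonzero(~a & m))
    return OverlapCounts(tp, fp, fn, convention)


def depthwise_overlap(
    auto_volume: np.ndarray,
    reference_volume: np.ndarray,
    slab_um: float = 40.0,
    voxel_z_um: float = 2.0,
    on_mips: bool = True,
    max_depth_um: float | None = None,
    convention: str = "default",
) -> tuple[list[OverlapCounts], dict[str, DepthProfile]]:
    """Overlap metrics per consecutive depth slab.

    With ``on_mips`` (the default) the two masks are max-projected over
    each slab before counting, matching MIP-based manual comparisons;
    otherwise all voxels of the slab are counted.  Returns the per-slab
    counts plus depth profiles (bin centers in µm) for every defined rate.
    """
    a = np.asarray(auto_volume).astype(bool)
    m = np.asarray(reference_volume).astype(bool)
    if a.shape != m.shape:
        raise ValueError("mask shapes differ")
    n_slices = int(round(slab_um / voxel_z_um))
    if n_slices < 1:
        raise ValueError("slab thinner than one slice")
    nz = a.shape[0]
    max_z = nz if max_depth_um is None else min(nz, int(round(max_depth_um / voxel_z_um)))
    counts: list[OverlapCounts] = []
    centers: list[float] = []
    for i0 in range(0, max_z, n_slices):
        i1 = min(max_z, i0 + n_slices)
        if on_mips:
            aa = a[i0:i1].max(axis=0)
            mm = m[i0:i1].max(axis=0)
        else:
            aa, mm = a[i0:i1], m[i0:i1]
        counts.append(overlap_metrics(aa, mm, convention))
        centers.append(0.5 * (i0 + i1) * voxel_z_um)

    profiles: dict[str, DepthProfile] = {}
    for name in ("tp_rate", "fp_rate", "fn_rate", "precision", "recall"):
        d, v, n = [], [], []
        for c, oc in zip(centers, counts):
            val = getattr(oc, name)
            if val is None:
                continue
            d.append(c)
            v.append(val)
            n.append(oc.n_reference if name != "fp_rate" else oc.n_auto)
        if d:
            profiles[name] = DepthProfile(np.asarray(d), np.asarray(v), name, np.asarray(n))
    return counts, profiles


# --------------------------------------------------------------------------
# Perfusion completeness
# --------------------------------------------------------------------------


def classify_perfusion(
    branches: list[tuple[float, float]],
) -> tuple[list[bool], float]:
    """Classify vessel branches as perfused from their stained length.

    A branch is non-perfused iff more than half of its length is unstained,
    i.e. (length − stained) / length > 0.5 (strict).  Returns the per-branch
    perfused flags and the percentage of perfused branches.
    """
    if not branches:
        raise ValueError("no branches given")
    flags = []
    for length, stained in branches:
        if length <= 0:
            raise ValueError("zero-length branch")
        if stained > length + 1e-12 or stained < 0:
            raise ValueError("stained length must be in [0, branch length]")
        flags.append((length - stained) / length <= 0.5)
    percent = 100.0 * sum(flags) / len(flags)
    return flags, percent
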