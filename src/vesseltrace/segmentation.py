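"""Unsupervised two-class Markov-random-field segmentation of vessel stacks.

The model is a hidden MRF with Gaussian emissions: each voxel label
l ∈ {0 (background), 1 (vessel)} has intensity I ~ N(μ_l, σ²_l), and labels
are coupled by a homogeneous Potts prior over the 6-connected neighborhood.
The posterior energy to minimize is

    E(l) = Σ_v [ (I_v − μ_{l_v})² / (2σ²_{l_v}) + ½·ln(2π σ²_{l_v}) ]
           + β · #{6-neighbor pairs with unequal labels}

Inference is iterated conditional modes (ICM) interleaved with
maximum-likelihood re-estimation of the class parameters (HMRF-EM style):
both steps can only lower the energy, so the outer energy trace is
non-increasing.  An ICM sweep updates the two checkerboard parity classes in
turn; voxels within one parity class share no 6-neighbor pairs, so the
vectorized parallel update is exact coordinate descent.  Ties go to the
background label.

Intensities are z-scored internally, which makes the default coupling
β = 1 transferable across bit depths and makes the labeling invariant to
affine intensity shifts.  Classical global-threshold baselines
(Otsu/isodata/mean) are provided for comparison, along with a blockwise
driver for stacks too large to label in one piece.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import filters as _skfilters

__all__ = [
    "MRFModel",
    "HMRFConfig",
    "SegmentationResult",
    "init_labels",
    "mrf_energy",
    "icm_sweep",
    "icm_optimize",
    "estimate_params",
    "hmrf_segment",
    "threshold_segment",
    "segment_blockwise",
]

VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class MRFModel:
    """Two-class Gaussian emission + Potts coupling parameters.

    ``beta`` may be a scalar (equal coupling on all axes) or a
    ``(beta_z, beta_y, beta_x)`` triple for anisotropy-aware smoothing.
    Class 1 is the vessel/foreground class by convention (μ₁ > μ₀).
    """

    mu0: float
    mu1: float
    var0: float
    var1: float
    beta: float | tuple[float, float, float] = 1.0
    max_iter: int = 20
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.var0 < VAR_FLOOR or self.var1 < VAR_FLOOR:
            raise ValueError(f"class variance below floor {VAR_FLOOR}")
        if not self.mu1 > self.mu0:
            raise ValueError("convention requires mu1 > mu0 (class 1 = vessel)")
        if np.any(np.asarray(self.beta, dtype=float) < 0):
            raise ValueError("Potts coupling beta must be >= 0")

    @property
    def beta_axes(self) -> np.ndarray:
        b = np.asarray(self.beta, dtype=float)
        return np.broadcast_to(b, (3,)).copy()


@dataclass(frozen=True)
class HMRFConfig:
    """Settings of the outer HMRF-EM loop."""

    beta: float | tuple[float, float, float] = 1.0
    max_iter: int = 20
    tol: float = 1e-4  # relative energy change declaring convergence
    init: str = "otsu"  # otsu | kmeans2
    sweeps_per_iter: int = 2
    standardize: bool = True
    var_floor: float = VAR_FLOOR


@dataclass
class SegmentationResult:
    labels: np.ndarray  # uint8 {0, 1}
    energy: float
    energy_trace: list[float]
    iterations: int
    converged: bool
    model: MRFModel
    norm_mean: float = 0.0  # standardization applied to intensities
    norm_sd: float = 1.0


# --------------------------------------------------------------------------
# Initialization
# --------------------------------------------------------------------------


def init_labels(volume: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Initial binary labeling; foreground is always the higher-mean class."""
    vol = np.asarray(volume)
    if vol.max() == vol.min():
        raise ValueError("degenerate input: no threshold exists")
    if method == "otsu":
        thr = _skfilters.threshold_otsu(vol)
        return (vol > thr).astype(np.uint8)
    if method == "kmeans2":
        flat = vol.astype(np.float64).ravel()
        c0, c1 = np.percentile(flat, [25.0, 75.0])
        if c0 == c1:
            c0, c1 = flat.min(), flat.max()
        for _ in range(100):
            mid = 0.5 * (c0 + c1)
            hi = flat > mid
            n0, n1 = (~hi).sum(), hi.sum()
            if n0 == 0 or n1 == 0:
                break
            new0, new1 = flat[~hi].mean(), flat[hi].mean()
            if new0 == c0 and new1 == c1:
                break
            c0, c1 = new0, new1
        return (vol > 0.5 * (c0 + c1)).astype(np.uint8)
    raise ValueError(f"unknown initialization method {method!r}")


# --------------------------------------------------------------------------
# Energy
# --------------------------------------------------------------------------


def _data_terms(volume: np.ndarray, model: MRFModel) -> tuple[np.ndarray, np.ndarray]:
    v = volume.astype(np.float64)
    d0 = (v - model.mu0) ** 2 / (2.0 * model.var0) + 0.5 * np.log(2 * np.pi * model.var0)
    d1 = (v - model.mu1) ** 2 / (2.0 * model.var1) + 0.5 * np.log(2 * np.pi * model.var1)
    return d0, d1


def mrf_energy(volume: np.ndarray, labels: np.ndarray, model: MRFModel) -> float:
    """Posterior energy of a labeling; each unordered neighbor pair once."""
    if volume.shape != labels.shape:
        raise ValueError("volume and labels shapes differ")
    d0, d1 = _data_terms(volume, model)
    lab = labels.astype(bool)
    data = float(np.where(lab, d1, d0).sum())
    pair = 0.0
    betas = model.beta_axes
    for ax in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[ax] = slice(None, -1)
        b[ax] = slice(1, None)
        pair += betas[ax] * float((lab[tuple(a)] != lab[tuple(b)]).sum())
    return data + pair


def _neighbor_sums(labels: np.ndarray, betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel β-weighted sum of neighbor labels and of neighbor counts."""
    lab = labels.astype(np.float32)
    S = np.zeros(lab.shape, dtype=np.float32)
    C = np.zeros(lab.shape, dtype=np.float32)
    for ax in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[ax] = slice(None, -1)
        b[ax] = slice(1, None)
        a, b = tuple(a), tuple(b)
        w = np.float32(betas[ax])
        S[a] += w * lab[b]
        S[b] += w * lab[a]
        C[a] += w
        C[b] += w
    return S, C


_parity_cache: dict[tuple[int, int, int], np.ndarray] = {}


def _parity(shape: tuple[int, int, int]) -> np.ndarray:
    if shape not in _parity_cache:
        iz = np.arange(shape[0])[:, None, None]
        iy = np.arange(shape[1])[None, :, None]
        ix = np.arange(shape[2])[None, None, :]
        _parity_cache[shape] = ((iz + iy + ix) & 1).astype(np.uint8)
        if len(_parity_cache) > 8:
            _parity_cache.pop(next(iter(_parity_cache)))
    return _parity_cache[shape]


def icm_sweep(
    volume: np.ndarray,
    labels: np.ndarray,
    model: MRFModel,
    _data: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """One full ICM sweep: coordinate descent over both checkerboard phases.

    Each voxel takes the label minimizing its local conditional energy
    (data term + β-weighted disagreement with its 6-neighbors); ties go to
    background.  The total energy never increases.
    """
    if volume.shape != labels.shape:
        raise ValueError("volume and labels shapes differ")
    d0, d1 = _data if _data is not None else _data_terms(volume, model)
    betas = model.beta_axes
    lab = labels.astype(np.uint8).copy()
    par = _parity(lab.shape)
    for phase in (0, 1):
        S, C = _neighbor_sums(lab, betas)
        cost0 = d0 + S
        cost1 = d1 + (C - S)
        new = (cost1 < cost0)  # strict: ties -> background
        sel = par == phase
        lab[sel] = new[sel]
    return lab


def icm_optimize(
    volume: np.ndarray,
    labels: np.ndarray,
    model: MRFModel,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Sweep with fixed parameters until the labeling is a fixed point."""
    data = _data_terms(volume, model)
    lab = labels.astype(np.uint8)
    for _ in range(max_sweeps):
        new = icm_sweep(volume, lab, model, _data=data)
        if np.array_equal(new, lab):
            break
        lab = new
    return lab


# --------------------------------------------------------------------------
# Parameter estimation
# --------------------------------------------------------------------------


def estimate_params(
    volume: np.ndarray,
    labels: np.ndarray,
    prev: MRFModel | None = None,
    var_floor: float = VAR_FLOOR,
) -> tuple[float, float, float, float]:
    """Per-class sample mean and (floored) variance.

    If a class is empty its parameters are carried over from ``prev`` with a
    warning (and fall back to the global statistics when no ``prev`` is
    given).
    """
    v = np.asarray(volume, dtype=np.float64)
    lab = np.asarray(labels).astype(bool)
    out = []
    for cls, sel in ((0, ~lab), (1, lab)):
        if sel.any():
            x = v[sel]
            out.append((float(x.mean()), max(float(x.var()), var_floor)))
        else:
            warnings.warn(f"class {cls} is empty; keeping previous parameters")
            if prev is not None:
                mu = prev.mu0 if cls == 0 else prev.mu1
                var = prev.var0 if cls == 0 else prev.var1
            else:
                mu, var = float(v.mean()), max(float(v.var()), var_floor)
            out.append((mu, var))
    (mu0, var0), (mu1, var1) = out
    return mu0, mu1, var0, var1


# --------------------------------------------------------------------------
# Full segmenters
# --------------------------------------------------------------------------


def hmrf_segment(volume: np.ndarray, config: HMRFConfig | None = None) -> SegmentationResult:
    """HMRF-EM segmentation: alternate ICM sweeps and parameter re-estimation.

    Stops when the relative energy change drops below ``config.tol`` or
    after ``config.max_iter`` outer iterations.  Deterministic for a fixed
    input and configuration.
    """
    if config is None:
        config = HMRFConfig()
    vol = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(vol).all():
        raise ValueError("volume contains non-finite values")
    mean, sd = float(vol.mean()), float(vol.std())
    if sd == 0.0:
        raise ValueError("degenerate input: no threshold exists")
    if config.standardize:
        vol = (vol - mean) / sd
    else:
        mean, sd = 0.0, 1.0

    labels = init_labels(vol, config.init)
    mu0, mu1, var0, var1 = estimate_params(vol, labels, var_floor=config.var_floor)
    if not mu1 > mu0:  # defensive: init guarantees higher-mean foreground
        labels = 1 - labels
        mu0, mu1, var0, var1 = mu1, mu0, var1, var0
    model = MRFModel(mu0, mu1, var0, var1, beta=config.beta,
                     max_iter=config.max_iter, tol=config.tol)

    trace = [mrf_energy(vol, labels, model)]
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        data = _data_terms(vol, model)
        for _ in range(max(1, config.sweeps_per_iter)):
            new = icm_sweep(vol, labels, model, _data=data)
            if np.array_equal(new, labels):
                break
            labels = new
        mu0, mu1, var0, var1 = estimate_params(
            vol, labels, prev=model, var_floor=config.var_floor
        )
        if not mu1 > mu0:
            labels = 1 - labels
            mu0, mu1, var0, var1 = mu1, mu0, var1, var0
        model = replace(model, mu0=mu0, mu1=mu1, var0=var0, var1=var1)
        e = mrf_energy(vol, labels, model)
        trace.append(e)
        if trace[-2] - e <= config.tol * abs(trace[-2]):
            converged = True
            break

    return SegmentationResult(
        labels=labels.astype(np.uint8),
        energy=trace[-1],
        energy_trace=trace,
        iterations=iterations,
        converged=converged,
        model=model,
        norm_mean=mean,
        norm_sd=sd,
    )


_THRESHOLD_METHODS = {
    "otsu": _skfilters.threshold_otsu,
    "isodata": _skfilters.threshold_isodata,
    "mean": _skfilters.threshold_mean,
}


def threshold_segment(volume: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Classical global-threshold baseline; foreground = above threshold."""
    if method not in _THRESHOLD_METHODS:
        raise ValueError(
            f"unknown thresholding method {method!r}; "
            f"choose from {sorted(_THRESHOLD_METHODS)}"
        )
    vol = np.asarray(volume)
    if vol.max() == vol.min():
        raise ValueError("degenerate input: no threshold exists")
    thr = _THRESHOLD_METHODS[method](vol)
    return (vol > thr).astype(np.uint8)


def segment_blockwise(
    volume: np.ndarray,
    config: HMRFConfig | None = None,
    block_shape: tuple[int, int, int] = (64, 256, 256),
    halo: int = 8,
    subsample_target: int = 2_000_000,
) -> SegmentationResult:
    """Blockwise HMRF for stacks too large to label in one piece.

    Class parameters are fitted once on a strided subsample of the whole
    volume and then frozen, so labels are consistent across blocks.  Each
    block is labelled with fixed-parameter ICM over an extended region with
    ``halo`` voxels of overlap; the halo is discarded on write-back.
    """
    if config is None:
        config = HMRFConfig()
    if halo < 1:
        raise ValueError("halo must be >= 1 voxel")
    if any(b < 2 * halo for b in block_shape):
        raise ValueError("block smaller than twice the halo")
    vol = np.asarray(volume, dtype=np.float64)

    stride = max(1, int(round((vol.size / subsample_target) ** (1.0 / 3.0))))
    sub = vol[::stride, ::stride, ::stride]
    fit = hmrf_segment(sub, config)
    model = fit.model
    zvol = (vol - fit.norm_mean) / fit.norm_sd

    d0f, d1f = None, None  # computed per block below
    labels = np.zeros(vol.shape, dtype=np.uint8)
    shape = vol.shape
    for z0 in range(0, shape[0], block_shape[0]):
        for y0 in range(0, shape[1], block_shape[1]):
            for x0 in range(0, shape[2], block_shape[2]):
                z1 = min(shape[0], z0 + block_shape[0])
                y1 = min(shape[1], y0 + block_shape[1])
                x1 = min(shape[2], x0 + block_shape[2])
                ez0, ey0, ex0 = max(0, z0 - halo), max(0, y0 - halo), max(0, x0 - halo)
                ez1 = min(shape[0], z1 + halo)
                ey1 = min(shape[1], y1 + halo)
                ex1 = min(shape[2], x1 + halo)
                block = zvol[ez0:ez1, ey0:ey1, ex0:ex1]
                d0f, d1f = _data_terms(block, model)
                init = (d1f < d0f).astype(np.uint8)  # ML start, frozen params
                lab = icm_optimize(block, init, model, max_sweeps=config.max_iter)
                labels[z0:z1, y0:y1, x0:x1] = lab[
                    z0 - ez0 : z0 - ez0 + (z1 - z0),
                    y0 - ey0 : y0 - ey0 + (y1 - y0),
                    x0 - ex0 : x0 - ex0 + (x1 - x0),
                ]
    energy = mrf_energy(zvol, labels, model)
    return SegmentationResult(
        labels=labels,
        energy=energy,
        energy_trace=[energy],
        iterations=fit.iterations,
        converged=fit.converged,
        model=model,
        norm_mean=fit.norm_mean,
        norm_sd=fit.norm_sd,
    )
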