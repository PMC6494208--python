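"""Whole-volume searchlight decoding, map smoothing, and group maps.

A sphere of radius 2 voxels (at most 33 voxels) is centred on every
in-mask voxel; the voxels inside sphere-and-mask form the feature set
for within-format pairwise decoding, giving one accuracy map per
format. Maps are smoothed with a mask-aware Gaussian kernel (8 mm FWHM
in the study) and compared between groups voxel-wise with a two-sample
t-test whose family-wise error is controlled by max-statistic
permutation of the group labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .decoding import CVSpec, ClassifierSpec, pairwise_decoding_matrix
from .errors import ConfigurationError, DataError
from .simulate import VolumetricPatterns

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SphereStencil:
    radius: int
    offsets: tuple[tuple[int, int, int], ...]


def sphere_offsets(radius: int) -> SphereStencil:
    """All integer offsets with squared norm <= radius^2, lexicographic.

    Radius 2 yields the study's 33-voxel sphere.
    """
    if radius < 0:
        raise ConfigurationError(f"radius must be >= 0, got {radius}")
    r = int(radius)
    offsets = tuple(
        (i, j, k)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
        for k in range(-r, r + 1)
        if i * i + j * j + k * k <= r * r
    )
    return SphereStencil(radius=r, offsets=offsets)


@dataclass
class AccuracyMap:
    data: np.ndarray  # 3-D accuracies, NaN outside mask
    mask: np.ndarray  # 3-D bool
    smoothing_fwhm_mm: float | None = None


def stencil_voxels(
    center: tuple[int, int, int],
    stencil: SphereStencil,
    mask: np.ndarray,
) -> list[tuple[int, int, int]]:
    """In-mask, in-bounds voxels covered by the stencil at ``center``."""
    shape = mask.shape
    out = []
    for off in stencil.offsets:
        v = (center[0] + off[0], center[1] + off[1], center[2] + off[2])
        if all(0 <= v[d] < shape[d] for d in range(3)) and mask[v]:
            out.append(v)
    return out


def searchlight_map(
    volume: VolumetricPatterns,
    stencil: SphereStencil,
    cv: CVSpec,
    spec: ClassifierSpec | None = None,
    pairs: list[tuple[int, int]] | None = None,
    seed: int | None = None,
) -> AccuracyMap:
    """Mean pairwise decoding accuracy at every in-mask sphere centre.

    ``pairs`` selects the condition pairs to average (e.g. one format's
    within-format pairs); default: all pairs. Centres whose sphere holds
    fewer than 2 in-mask voxels stay NaN.
    """
    spec = spec or ClassifierSpec()
    mask = volume.mask
    if not mask.any():
        raise DataError("empty mask")
    if volume.data.shape[2:] != mask.shape:
        raise DataError(
            f"patterns grid {volume.data.shape[2:]} != mask grid {mask.shape}"
        )
    n_cond = volume.data.shape[1]
    if pairs is None:
        pairs = list(itertools.combinations(range(n_cond), 2))
    rng = np.random.default_rng(cv.seed if seed is None else seed)
    out = np.full(mask.shape, np.nan)
    for center in zip(*np.nonzero(mask)):
        voxels = stencil_voxels(center, stencil, mask)
        if len(voxels) < 2:
            continue
        vi = tuple(np.array(v) for v in zip(*voxels))
        patterns = volume.data[:, :, vi[0], vi[1], vi[2]]  # (R, C, V)
        matrix = pairwise_decoding_matrix(
            patterns, cv, spec, pairs=pairs,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        out[center] = np.nanmean([matrix[i, j] for i, j in pairs])
    return AccuracyMap(data=out, mask=mask)


def smooth_map(
    amap: AccuracyMap, fwhm_mm: float, voxel_size_mm: float | tuple[float, ...] = 1.0
) -> AccuracyMap:
    """Mask-aware Gaussian smoothing with source-normalised weights.

    Each in-mask voxel's kernel mass is renormalised over the in-mask
    portion of its kernel before convolution, so the in-mask sum (hence
    mean) is preserved exactly and a delta spreads into a kernel that
    integrates to 1 within the mask. FWHM 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ConfigurationError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return AccuracyMap(amap.data.copy(), amap.mask, smoothing_fwhm_mm=0.0)
    vs = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    sigma = fwhm_mm * FWHM_TO_SIGMA / vs
    mask = amap.mask
    m = mask.astype(float)
    x = np.where(mask, np.nan_to_num(amap.data), 0.0)
    w = ndimage.gaussian_filter(m, sigma, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        src = np.where(mask & (w > 0), x / w, 0.0)
    sm = ndimage.gaussian_filter(src, sigma, mode="constant")
    out = np.where(mask, sm, np.nan)
    return AccuracyMap(out, mask, smoothing_fwhm_mm=float(fwhm_mm))


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised pooled-variance two-sample t over the last stacking axis 0."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))


@dataclass
class GroupMapResult:
    tmap: np.ndarray  # 3-D t-statistics (NaN outside mask)
    p_fwe: np.ndarray  # 3-D permutation FWE p-values
    surviving: np.ndarray  # 3-D bool, |t| significant at alpha
    peaks: pd.DataFrame  # surviving voxels sorted by |t|
    null_max: np.ndarray  # permutation distribution of max |t|


def group_compare_maps(
    maps_a: list[AccuracyMap] | np.ndarray,
    maps_b: list[AccuracyMap] | np.ndarray,
    mask: np.ndarray | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> GroupMapResult:
    """Voxel-wise group comparison with max-statistic permutation FWE.

    Accuracy-minus-chance maps are compared with a two-sample t-test per
    voxel; the null distribution of the maximum |t| over the mask is
    built from random group-label relabelings, and a voxel survives when
    its FWE-corrected p = (1 + #{max-null >= |t|}) / (n_perm + 1) <= alpha.
    """

    def stack(maps):
        if isinstance(maps, np.ndarray):
            return maps
        return np.stack([m.data for m in maps])

    a = stack(maps_a)
    b = stack(maps_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DataError("need >= 2 subjects per group")
    if mask is None:
        mask = (
            maps_a[0].mask
            if not isinstance(maps_a, np.ndarray)
            else np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
        )
    if a.shape[1:] != mask.shape or b.shape[1:] != mask.shape:
        raise DataError("maps and mask grids differ")

    av = a[:, mask] - 0.5
    bv = b[:, mask] - 0.5
    t_obs = _two_sample_t(av, bv)

    both = np.concatenate([av, bv])
    na = av.shape[0]
    n = both.shape[0]
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        null_max[k] = np.nanmax(np.abs(_two_sample_t(both[perm[:na]], both[perm[na:]])))

    p_vox = (1 + (null_max[None, :] >= np.abs(t_obs)[:, None]).sum(axis=1)) / (
        n_perm + 1
    )
    tmap = np.full(mask.shape, np.nan)
    pmap = np.full(mask.shape, np.nan)
    tmap[mask] = t_obs
    pmap[mask] = p_vox
    surviving = np.zeros(mask.shape, dtype=bool)
    surviving[mask] = p_vox <= alpha

    coords = np.argwhere(surviving)
    peaks = pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "t": tmap[surviving],
            "p_fwe": pmap[surviving],
        }
    ).sort_values("t", key=np.abs, ascending=False).reset_index(drop=True)
    return GroupMapResult(
        tmap=tmap, p_fwe=pmap, surviving=surviving, peaks=peaks, null_max=null_max
    )
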