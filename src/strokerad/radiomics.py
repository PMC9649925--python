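"""Radiomic feature extraction from ADC volumes under a lesion mask.

The feature vector has a fixed, manifest-pinned layout of 513 entries:
57 features (18 first-order + 23 gray-level co-occurrence + 16 run-length)
computed in the image domain and again in each of the 8 sub-bands of a
one-level undecimated 3D Haar wavelet decomposition (LLL ... HHH), using the
same lesion mask throughout (sub-bands are shape-preserving).

Texture matrices are built on gray levels quantized to ``n_levels`` over the
min-max range inside the mask, accumulated over the 13 unique distance-1
directions of the 3D 26-neighborhood; co-occurrence matrices are symmetrized
and direction-summed before features are computed, run-length matrices are
direction-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pywt

from .errors import DataError, ExclusionError, ShapeError

MIN_LESION_VOXELS = 50  # inclusion rule: lesions below this are excluded

SUBBAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

FIRST_ORDER_NAMES = (
    "fo_mean", "fo_median", "fo_minimum", "fo_maximum", "fo_range",
    "fo_variance", "fo_std", "fo_skewness", "fo_kurtosis", "fo_energy",
    "fo_entropy", "fo_uniformity", "fo_p10", "fo_p90", "fo_iqr",
    "fo_mad", "fo_rmad", "fo_rms",
)

GLCM_NAMES = (
    "glcm_autocorrelation", "glcm_joint_average", "glcm_cluster_prominence",
    "glcm_cluster_shade", "glcm_cluster_tendency", "glcm_contrast",
    "glcm_correlation", "glcm_difference_average", "glcm_difference_entropy",
    "glcm_difference_variance", "glcm_joint_energy", "glcm_joint_entropy",
    "glcm_imc1", "glcm_imc2", "glcm_idm", "glcm_idmn", "glcm_id", "glcm_idn",
    "glcm_inverse_variance", "glcm_maximum_probability", "glcm_sum_average",
    "glcm_sum_entropy", "glcm_sum_of_squares",
)

GLRLM_NAMES = (
    "glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_glnn", "glrlm_rln",
    "glrlm_rlnn", "glrlm_rp", "glrlm_glv", "glrlm_rv", "glrlm_re",
    "glrlm_lglre", "glrlm_hglre", "glrlm_srlgle", "glrlm_srhgle",
    "glrlm_lrlgle", "glrlm_lrhgle",
)

TEXTURE_NAMES = GLCM_NAMES + GLRLM_NAMES

#: the 13 unique distance-1 directions of the 26-neighborhood (up to sign)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass(frozen=True)
class QuantizationSpec:
    """Gray-level quantization for texture matrices: ``n_levels`` equal-width
    bins over the min-max intensity range inside the mask."""

    n_levels: int = 32

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")


@dataclass
class FeatureVector:
    """Ordered, named radiomic feature vector with per-slot provenance."""

    names: list[str]
    values: np.ndarray
    domains: list[str]
    families: list[str]
    subject_id: str | None = None

    def __len__(self) -> int:
        return len(self.names)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.subject_id)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def feature_manifest() -> pd.DataFrame:
    """The pinned feature layout: 57 image-domain + 8 x 57 wavelet features.

    Returns a frame with columns ``name``, ``domain``, ``family`` in extraction
    order; its length is the feature-count contract (513).
    """
    rows = []
    for domain in ("image",) + tuple(f"wavelet-{b}" for b in SUBBAND_NAMES):
        tag = domain.replace("wavelet-", "w")
        for base in FIRST_ORDER_NAMES:
            rows.append((f"{tag}_{base}", domain, "intensity"))
        for base in TEXTURE_NAMES:
            rows.append((f"{tag}_{base}", domain, "texture"))
    return pd.DataFrame(rows, columns=["name", "domain", "family"])


# ---------------------------------------------------------------------------
# wavelet sub-bands
# ---------------------------------------------------------------------------

def wavelet_subbands(volume: np.ndarray, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """One-level undecimated (stationary) 3D wavelet decomposition.

    Returns the 8 sub-bands keyed LLL..HHH, each with the shape of the input
    so the original lesion mask applies unchanged.  Axis order of the band
    label follows the array axes (first letter = axis 0).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3 or min(volume.shape) < 2:
        raise ShapeError(f"need a 3D volume with every dim >= 2, got shape {volume.shape}")
    # swt needs even extents: edge-pad by one where odd, crop after
    pads = [(0, s % 2) for s in volume.shape]
    padded = np.pad(volume, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet=wavelet, level=1, start_level=0,
                       trim_approx=False, norm=False)[0]
    out: dict[str, np.ndarray] = {}
    sl = tuple(slice(0, s) for s in volume.shape)
    for band in SUBBAND_NAMES:
        key = band.replace("L", "a").replace("H", "d")
        out[band] = np.ascontiguousarray(coeffs[key][sl])
    return out


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------

def intensity_features(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """The 18 first-order statistics of the manifest, from masked voxel values.

    Histogram entropy/uniformity use ``n_bins`` equal-width bins over the
    observed range.  Zero-variance conventions: skewness = kurtosis = 0,
    entropy = 0, uniformity = 1.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise DataError("intensity_features needs at least one voxel value")
    mean = float(v.mean())
    var = float(v.var())
    sd = float(np.sqrt(var))
    vmin, vmax = float(v.min()), float(v.max())
    p10, p25, p75, p90 = (float(x) for x in np.percentile(v, [10, 25, 75, 90]))
    # relative epsilon guards against summation rounding on constant regions
    if sd > 1e-12 * max(1.0, abs(mean)):
        z = (v - mean) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4) - 3.0)  # excess kurtosis
    else:
        skew = kurt = 0.0
    if vmax > vmin:
        hist, _ = np.histogram(v, bins=n_bins, range=(vmin, vmax))
        p = hist[hist > 0] / v.size
        entropy = float(-np.sum(p * np.log2(p)))
        uniformity = float(np.sum(p ** 2))
    else:
        entropy, uniformity = 0.0, 1.0
    robust = v[(v >= p10) & (v <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
    return {
        "fo_mean": mean,
        "fo_median": float(np.median(v)),
        "fo_minimum": vmin,
        "fo_maximum": vmax,
        "fo_range": vmax - vmin,
        "fo_variance": var,
        "fo_std": sd,
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_energy": float(np.sum(v ** 2)),
        "fo_entropy": entropy,
        "fo_uniformity": uniformity,
        "fo_p10": p10,
        "fo_p90": p90,
        "fo_iqr": p75 - p25,
        "fo_mad": float(np.mean(np.abs(v - mean))),
        "fo_rmad": rmad,
        "fo_rms": float(np.sqrt(np.mean(v ** 2))),
    }


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------

def quantize(volume: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Quantize masked voxels to integer levels 1..n_levels (min-max binning);
    voxels outside the mask are 0.  A constant region maps to level 1."""
    q = np.zeros(volume.shape, dtype=np.int32)
    vals = volume[mask]
    vmin, vmax = vals.min(), vals.max()
    if vmax > vmin:
        lev = np.floor((vals - vmin) / (vmax - vmin) * n_levels).astype(np.int32) + 1
        np.clip(lev, 1, n_levels, out=lev)
    else:
        lev = np.ones(vals.shape, dtype=np.int32)
    q[mask] = lev
    return q


def _bbox_crop(q: np.ndarray) -> np.ndarray:
    idx = np.nonzero(q)
    sl = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    return q[sl]


def _pair_shift(arr: np.ndarray, d: Sequence[int]):
    """Slices (sa, sb) such that arr[sa] and arr[sb] are the (v, v+d) pairs."""
    sa, sb = [], []
    for dim, step in zip(arr.shape, d):
        if step == 0:
            sa.append(slice(None)); sb.append(slice(None))
        elif step > 0:
            sa.append(slice(0, dim - step)); sb.append(slice(step, dim))
        else:
            sa.append(slice(-step, dim)); sb.append(slice(0, dim + step))
    return tuple(sa), tuple(sb)


def glcm_matrix(q: np.ndarray, n_levels: int,
                directions: Sequence[Sequence[int]] = DIRECTIONS_3D) -> np.ndarray:
    """Symmetric, direction-summed, normalized gray-level co-occurrence matrix
    from a quantized array (0 = outside mask, 1..n_levels inside)."""
    q = _bbox_crop(q)
    counts = np.zeros((n_levels + 1) * (n_levels + 1), dtype=np.int64)
    for d in directions:
        sa, sb = _pair_shift(q, d)
        a, b = q[sa].ravel(), q[sb].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        pair = a[ok].astype(np.int64) * (n_levels + 1) + b[ok]
        counts += np.bincount(pair, minlength=counts.size)
    mat = counts.reshape(n_levels + 1, n_levels + 1)[1:, 1:].astype(float)
    mat = mat + mat.T  # symmetrize
    total = mat.sum()
    if total == 0:  # single-voxel mask: behave like a constant region
        mat[0, 0] = 1.0
        total = 1.0
    return mat / total


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 23 co-occurrence features from a normalized GLCM ``p`` (L x L)."""
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    ux = float(np.sum(i * px))
    sx = float(np.sqrt(np.sum((i - ux) ** 2 * px)))
    # symmetric matrix: marginals coincide
    diff = np.abs(ii - jj)
    ssum = ii + jj
    k_diff = np.arange(0, L, dtype=float)
    p_diff = np.array([p[diff == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * L + 1, dtype=float)
    p_sum = np.array([p[ssum == k].sum() for k in k_sum])

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q))) if q.size else 0.0

    autoc = float(np.sum(ii * jj * p))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    corr = 1.0 if sx == 0 else float((autoc - ux * ux) / (sx * sx))
    davg = float(np.sum(k_diff * p_diff))
    hxy = ent(p.ravel())
    pxpy = np.outer(px, px)
    nz = pxpy > 0
    hxy1 = float(-np.sum(p[nz] * np.log2(pxpy[nz])))
    hxy2 = ent(pxpy.ravel())
    hx = ent(px)
    imc1 = 0.0 if hx == 0 else (hxy - hxy1) / hx
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off = diff > 0
    return {
        "glcm_autocorrelation": autoc,
        "glcm_joint_average": ux,
        "glcm_cluster_prominence": float(np.sum((ii + jj - 2 * ux) ** 4 * p)),
        "glcm_cluster_shade": float(np.sum((ii + jj - 2 * ux) ** 3 * p)),
        "glcm_cluster_tendency": float(np.sum((ii + jj - 2 * ux) ** 2 * p)),
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_difference_average": davg,
        "glcm_difference_entropy": ent(p_diff),
        "glcm_difference_variance": float(np.sum((k_diff - davg) ** 2 * p_diff)),
        "glcm_joint_energy": float(np.sum(p ** 2)),
        "glcm_joint_entropy": hxy,
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "glcm_idmn": float(np.sum(p / (1.0 + ((ii - jj) / L) ** 2))),
        "glcm_id": float(np.sum(p / (1.0 + diff))),
        "glcm_idn": float(np.sum(p / (1.0 + diff / L))),
        "glcm_inverse_variance": float(np.sum(p[off] / diff[off] ** 2)),
        "glcm_maximum_probability": float(p.max()),
        "glcm_sum_average": float(np.sum(k_sum * p_sum)),
        "glcm_sum_entropy": ent(p_sum),
        "glcm_sum_of_squares": float(np.sum((ii - ux) ** 2 * p)),
    }


def _shift_to(arr: np.ndarray, d: Sequence[int], fill=0) -> np.ndarray:
    """out[v] = arr[v + d], filled with ``fill`` where v+d leaves the array."""
    out = np.full(arr.shape, fill, dtype=arr.dtype)
    sa, sb = _pair_shift(arr, d)
    out[sa] = arr[sb]
    return out


def glrlm_matrix(q: np.ndarray, n_levels: int,
                 directions: Sequence[Sequence[int]] = DIRECTIONS_3D) -> tuple[np.ndarray, float]:
    """Direction-averaged gray-level run-length matrix.

    Returns ``(R, n_voxels)`` where ``R[i, r]`` is the mean (over directions)
    number of runs of level i+1 and length r+1.
    """
    q = _bbox_crop(q)
    valid = q > 0
    max_len = int(np.ceil(np.sqrt(sum(s ** 2 for s in q.shape)))) + 1
    mats = []
    for d in directions:
        nxt = _shift_to(q, d)
        same = valid & (nxt == q) & (nxt > 0)
        # chain[v] = length of the constant run starting at v along +d
        chain = valid.astype(np.int64)
        for _ in range(max_len):
            upd = np.where(same, _shift_to(chain, d) + 1, chain)
            if np.array_equal(upd, chain):
                break
            chain = upd
        prev_same = _shift_to(same, tuple(-x for x in d))
        start = valid & ~prev_same
        levels = q[start] - 1
        lengths = chain[start] - 1
        m = np.zeros((n_levels, max_len), dtype=np.int64)
        np.add.at(m, (levels, lengths), 1)
        mats.append(m)
    R = np.mean(mats, axis=0)
    return R, float(valid.sum())


def glrlm_features(R: np.ndarray, n_voxels: float) -> dict[str, float]:
    """The 16 run-length features from a run-length matrix ``R``."""
    nr = R.sum()
    if nr == 0:
        nr = 1.0
    L, M = R.shape
    i = np.arange(1, L + 1, dtype=float)[:, None]
    r = np.arange(1, M + 1, dtype=float)[None, :]
    p = R / nr
    gl = R.sum(axis=1)
    rl = R.sum(axis=0)
    mu_i = float(np.sum(i * p))
    mu_r = float(np.sum(r * p))
    pe = p[p > 0]
    return {
        "glrlm_sre": float(np.sum(R / r ** 2) / nr),
        "glrlm_lre": float(np.sum(R * r ** 2) / nr),
        "glrlm_gln": float(np.sum(gl ** 2) / nr),
        "glrlm_glnn": float(np.sum(gl ** 2) / nr ** 2),
        "glrlm_rln": float(np.sum(rl ** 2) / nr),
        "glrlm_rlnn": float(np.sum(rl ** 2) / nr ** 2),
        "glrlm_rp": float(nr / n_voxels),
        "glrlm_glv": float(np.sum((i - mu_i) ** 2 * p)),
        "glrlm_rv": float(np.sum((r - mu_r) ** 2 * p)),
        "glrlm_re": float(-np.sum(pe * np.log2(pe))),
        "glrlm_lglre": float(np.sum(R / i ** 2) / nr),
        "glrlm_hglre": float(np.sum(R * i ** 2) / nr),
        "glrlm_srlgle": float(np.sum(R / (i ** 2 * r ** 2)) / nr),
        "glrlm_srhgle": float(np.sum(R * i ** 2 / r ** 2) / nr),
        "glrlm_lrlgle": float(np.sum(R * r ** 2 / i ** 2) / nr),
        "glrlm_lrhgle": float(np.sum(R * i ** 2 * r ** 2) / nr),
    }


def texture_features(volume: np.ndarray, mask: np.ndarray,
                     q: QuantizationSpec = QuantizationSpec(),
                     directions: Sequence[Sequence[int]] = DIRECTIONS_3D) -> dict[str, float]:
    """The 39 texture features (23 GLCM + 16 GLRLM) of the manifest."""
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ShapeError(f"volume {volume.shape} vs mask {mask.shape}")
    if not mask.any():
        raise DataError("texture_features needs a non-empty mask")
    if not np.isfinite(volume[mask]).all():
        raise DataError("non-finite voxel values inside mask")
    qa = quantize(np.asarray(volume, dtype=float), mask, q.n_levels)
    out = glcm_features(glcm_matrix(qa, q.n_levels, directions))
    R, nvox = glrlm_matrix(qa, q.n_levels, directions)
    out.update(glrlm_features(R, nvox))
    return out


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract_features(adc: np.ndarray, mask: np.ndarray,
                     q: QuantizationSpec = QuantizationSpec(),
                     subject_id: str | None = None,
                     wavelet: str = "haar",
                     enforce_min_size: bool = True) -> FeatureVector:
    """Extract the full 513-entry feature vector from an ADC volume.

    The mask is the (cleaned) DWI-derived lesion mask; it is applied unchanged
    to the image domain and to every wavelet sub-band.  Masks below the
    50-voxel inclusion threshold raise :class:`ExclusionError`.
    """
    adc = np.asarray(adc, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if adc.shape != mask.shape:
        raise ShapeError(f"adc {adc.shape} vs mask {mask.shape}")
    n_vox = int(mask.sum())
    if enforce_min_size and n_vox < MIN_LESION_VOXELS:
        raise ExclusionError(
            f"lesion has {n_vox} voxels, below the {MIN_LESION_VOXELS}-voxel inclusion rule")
    if n_vox == 0:
        raise DataError("empty mask")

    domains: dict[str, np.ndarray] = {"image": adc}
    for band, vol in wavelet_subbands(adc, wavelet=wavelet).items():
        domains[f"wavelet-{band}"] = vol

    manifest = feature_manifest()
    values: list[float] = []
    for domain, vol in domains.items():
        fo = intensity_features(vol[mask])
        tx = texture_features(vol, mask, q)
        values.extend(fo[k] for k in FIRST_ORDER_NAMES)
        values.extend(tx[k] for k in TEXTURE_NAMES)
    return FeatureVector(
        names=list(manifest["name"]),
        values=np.asarray(values, dtype=float),
        domains=list(manifest["domain"]),
        families=list(manifest["family"]),
        subject_id=subject_id,
    )


def extract_cohort_features(volumes: Sequence[np.ndarray], masks: Sequence[np.ndarray],
                            subject_ids: Sequence[str] | None = None,
                            q: QuantizationSpec = QuantizationSpec()) -> pd.DataFrame:
    """Feature table (subjects x 513) for a cohort; rows indexed by subject id."""
    rows = []
    ids = subject_ids if subject_ids is not None else [f"sub-{i:04d}" for i in range(len(volumes))]
    for sid, vol, msk in zip(ids, volumes, masks):
        rows.append(extract_features(vol, msk, q, subject_id=sid).to_series())
    return pd.DataFrame(rows)
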