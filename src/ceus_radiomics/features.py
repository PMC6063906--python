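"""Radiomic feature extraction: the 235-feature vector.

Per scan, four imaging biomarker classes are computed from a denoised
reference B-mode image (temporal mean of the denoised pre-destruction
frames) and from the vessel segmentation:

* 14 first-order intensity statistics over the ROI;
* 30 textural features: 19 from the grey-level co-occurrence matrix
  (GLCM) and 11 from the grey-level run-length matrix (GLRLM), both on
  32-level quantized intensities, four 2-D directions averaged;
* 15 vascular features from the binary vessel mask, its skeleton, the
  vessel distance map and the replenishment fit (relative blood volume,
  network length, flow velocity, ...);
* 176 wavelet features: the level-1 undecimated (stationary) coiflet-1
  transform yields four full-resolution subbands (A, H, V, D); the 44
  intensity + texture features are recomputed on each.

14 + 30 + 15 + 176 = 235, enforced structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.ndimage import binary_erosion, convolve, distance_transform_edt
from skimage.measure import label
from skimage.morphology import disk, skeletonize

from .denoise import DenoiseParams, denoise_frame
from .phantom import CEUSSequence, ROIMask, ScanRecord, Study
from .segmentation import (ReplenishmentFit, VesselMask, detect_artifact_frames,
                           fit_replenishment, segment_vessels)

__all__ = [
    "QuantizationParams",
    "ExtractionParams",
    "FeatureVector",
    "FEATURE_NAMES",
    "FEATURE_CLASSES",
    "feature_class",
    "quantize",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "vascular_features",
    "wavelet_features",
    "extract_all",
    "extract_study",
]

# pixel offsets of the four 2-D directions (0, 45, 90, 135 degrees)
DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_FO_NAMES = ["energy", "entropy", "kurtosis", "maximum", "mean", "mad",
             "median", "minimum", "range", "rms", "skewness", "std",
             "uniformity", "variance"]
_GLCM_NAMES = ["autocorrelation", "cluster_prominence", "cluster_shade",
               "contrast", "correlation", "difference_entropy",
               "dissimilarity", "energy", "entropy", "homogeneity", "imc1",
               "imc2", "idmn", "max_probability", "sum_average",
               "sum_entropy", "sum_variance", "variance", "inverse_variance"]
_GLRLM_NAMES = ["SRE", "LRE", "GLN", "RLN", "RP", "LGLRE", "HGLRE",
                "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE"]
_VASC_NAMES = ["n_vessels", "mean_vessel_size", "median_vessel_size",
               "network_length", "dist_mean", "dist_std", "dist_max", "rbv",
               "rbv_periphery_core_ratio", "flow_velocity", "vascular_area",
               "max_vessel_size", "n_branch_points", "rbv_periphery",
               "rbv_core"]
_SUBBANDS = ("A", "H", "V", "D")


def _build_names() -> tuple[list[str], dict[str, str]]:
    names, classes = [], {}
    for n in _FO_NAMES:
        names.append(f"fo_{n}")
        classes[names[-1]] = "first_order"
    for n in _GLCM_NAMES:
        names.append(f"glcm_{n}")
        classes[names[-1]] = "textural"
    for n in _GLRLM_NAMES:
        names.append(f"glrlm_{n}")
        classes[names[-1]] = "textural"
    for n in _VASC_NAMES:
        names.append(f"vasc_{n}")
        classes[names[-1]] = "vascular"
    for sb in _SUBBANDS:
        for n in _FO_NAMES:
            names.append(f"wav{sb}_fo_{n}")
            classes[names[-1]] = "wavelet"
        for n in _GLCM_NAMES:
            names.append(f"wav{sb}_glcm_{n}")
            classes[names[-1]] = "wavelet"
        for n in _GLRLM_NAMES:
            names.append(f"wav{sb}_glrlm_{n}")
            classes[names[-1]] = "wavelet"
    return names, classes


FEATURE_NAMES, FEATURE_CLASSES = _build_names()
assert len(FEATURE_NAMES) == 235
BIOMARKER_CLASSES = ("first_order", "textural", "vascular", "wavelet")


def feature_class(name: str) -> str:
    """Biomarker class of a feature name."""
    return FEATURE_CLASSES[name]


@dataclass(frozen=True)
class QuantizationParams:
    """Grey-level quantization: min-max over the ROI to ``n_levels`` bins."""

    n_levels: int = 32

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


def quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Map intensities to integer grey levels 1..n_levels (min-max over input)."""
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    q = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    return np.clip(q, 1, n_levels)


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def first_order_features(image: np.ndarray, roi: ROIMask,
                         q: QuantizationParams | None = None) -> dict[str, float]:
    """The 14 first-order intensity statistics over ROI pixels.

    Moments use population (1/n) normalization; kurtosis is the non-excess
    fourth standardized moment; entropy and uniformity are computed on the
    quantized grey-level histogram.
    """
    if q is None:
        q = QuantizationParams()
    x = np.asarray(image, dtype=np.float64)[roi.mask]
    if x.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    mean = x.mean()
    var = x.var()
    m2 = var
    cen = x - mean
    skew = float(np.mean(cen ** 3) / m2 ** 1.5) if m2 > 0 else 0.0
    kurt = float(np.mean(cen ** 4) / m2 ** 2) if m2 > 0 else 0.0
    levels = quantize(x, q.n_levels)
    p = np.bincount(levels, minlength=q.n_levels + 1)[1:] / x.size
    return {
        "fo_energy": float(np.sum(x * x)),
        "fo_entropy": float(-np.sum(_xlog2(p))),
        "fo_kurtosis": kurt,
        "fo_maximum": float(x.max()),
        "fo_mean": float(mean),
        "fo_mad": float(np.mean(np.abs(cen))),
        "fo_median": float(np.median(x)),
        "fo_minimum": float(x.min()),
        "fo_range": float(np.ptp(x)),
        "fo_rms": float(np.sqrt(np.mean(x * x))),
        "fo_skewness": skew,
        "fo_std": float(np.sqrt(var)),
        "fo_uniformity": float(np.sum(p * p)),
        "fo_variance": float(var),
    }


def _quantized_roi_image(image: np.ndarray, roi: ROIMask, n_levels: int) -> np.ndarray:
    """Quantized image with 0 outside the ROI and levels 1..n inside."""
    qimg = np.zeros(image.shape, dtype=np.int64)
    qimg[roi.mask] = quantize(np.asarray(image, dtype=np.float64)[roi.mask], n_levels)
    return qimg


def glcm_matrix(qimg: np.ndarray, n_levels: int,
                directions: tuple[tuple[int, int], ...] = DIRECTIONS) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix averaged over directions.

    ``qimg`` holds grey levels 1..n inside the ROI and 0 outside; only
    pixel pairs with both members inside the ROI are counted.
    """
    h, w = qimg.shape
    acc = np.zeros((n_levels, n_levels), dtype=np.float64)
    n_dir = 0
    for dy, dx in directions:
        y0, y1 = max(0, -dy), h - max(0, dy)
        x0, x1 = max(0, -dx), w - max(0, dx)
        a = qimg[y0:y1, x0:x1]
        b = qimg[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        mat = np.zeros((n_levels, n_levels), dtype=np.float64)
        np.add.at(mat, (a[valid] - 1, b[valid] - 1), 1.0)
        mat = mat + mat.T  # symmetric: count both pair orders
        acc += mat / mat.sum()
        n_dir += 1
    if n_dir == 0:
        raise ValueError("no valid co-occurring pixel pairs inside the ROI")
    return acc / n_dir


def glcm_features(image: np.ndarray, roi: ROIMask,
                  q: QuantizationParams | None = None,
                  directions: tuple[tuple[int, int], ...] = DIRECTIONS,
                  prefix: str = "glcm_") -> dict[str, float]:
    """The 19 GLCM texture features on the direction-averaged matrix."""
    if q is None:
        q = QuantizationParams()
    if int(roi.mask.sum()) < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    qimg = _quantized_roi_image(image, roi, q.n_levels)
    p = glcm_matrix(qimg, q.n_levels, directions)
    n = q.n_levels
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)                       # marginal (symmetric: px == py)
    mu = float(np.sum(i * px))
    sd = float(np.sqrt(np.sum((i - mu) ** 2 * px)))

    # |i-j| and i+j marginal distributions
    k_diff = np.arange(0, n)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * n + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])

    hxy = float(-np.sum(_xlog2(p)))
    hx = float(-np.sum(_xlog2(px)))
    pxy = np.outer(px, px)
    mask_nz = pxy > 0
    hxy1 = float(-np.sum(p[mask_nz] * np.log2(pxy[mask_nz])))
    hxy2 = float(-np.sum(_xlog2(pxy)))

    corr = float((np.sum(ii * jj * p) - mu * mu) / (sd * sd)) if sd > 0 else 0.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))
    sum_avg = float(np.sum(k_sum * p_sum))

    off_diag = ii != jj
    inv_var = float(np.sum(p[off_diag] / (ii[off_diag] - jj[off_diag]) ** 2))

    vals = {
        "autocorrelation": float(np.sum(ii * jj * p)),
        "cluster_prominence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "cluster_shade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "contrast": float(np.sum((ii - jj) ** 2 * p)),
        "correlation": corr,
        "difference_entropy": float(-np.sum(_xlog2(p_diff))),
        "dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "energy": float(np.sum(p * p)),
        "entropy": hxy,
        "homogeneity": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "imc1": imc1,
        "imc2": imc2,
        "idmn": float(np.sum(p / (1.0 + (ii - jj) ** 2 / n ** 2))),
        "max_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": float(-np.sum(_xlog2(p_sum))),
        "sum_variance": float(np.sum((k_sum - sum_avg) ** 2 * p_sum)),
        "variance": float(sd * sd),
        "inverse_variance": inv_var,
    }
    return {prefix + k: vals[k] for k in _GLCM_NAMES}


def _line_runs(line: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant runs of a 1-D quantized line; level 0 breaks runs."""
    runs = []
    n = len(line)
    start = 0
    for t in range(1, n + 1):
        if t == n or line[t] != line[start]:
            if line[start] > 0:
                runs.append((int(line[start]), t - start))
            start = t
    return runs


def glrlm_matrix(qimg: np.ndarray, n_levels: int,
                 directions: tuple[tuple[int, int], ...] = DIRECTIONS) -> np.ndarray:
    """Run-length count matrix r(level, run_length) averaged over directions."""
    h, w = qimg.shape
    max_len = max(h, w)
    acc = np.zeros((n_levels, max_len), dtype=np.float64)
    for dy, dx in directions:
        mat = np.zeros((n_levels, max_len), dtype=np.float64)
        if (dy, dx) in ((0, 1), (0, -1)):
            lines = list(qimg)
        elif (dy, dx) in ((1, 0), (-1, 0)):
            lines = list(qimg.T)
        elif dy * dx < 0:  # 45 degrees (up-right): anti-diagonals
            lines = [np.flipud(qimg).diagonal(o) for o in range(-h + 1, w)]
        else:              # 135 degrees (down-right): main diagonals
            lines = [qimg.diagonal(o) for o in range(-h + 1, w)]
        for line in lines:
            for level, length in _line_runs(np.asarray(line)):
                mat[level - 1, length - 1] += 1.0
        acc += mat
    return acc / len(directions)


def glrlm_features(image: np.ndarray, roi: ROIMask,
                   q: QuantizationParams | None = None,
                   directions: tuple[tuple[int, int], ...] = DIRECTIONS,
                   prefix: str = "glrlm_") -> dict[str, float]:
    """The 11 GLRLM run-length features on the direction-averaged matrix."""
    if q is None:
        q = QuantizationParams()
    n_pix = int(roi.mask.sum())
    if n_pix < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    qimg = _quantized_roi_image(image, roi, q.n_levels)
    r = glrlm_matrix(qimg, q.n_levels, directions)
    n_runs = r.sum()
    i = np.arange(1, r.shape[0] + 1)[:, None].astype(np.float64)
    j = np.arange(1, r.shape[1] + 1)[None, :].astype(np.float64)
    vals = {
        "SRE": float(np.sum(r / j ** 2) / n_runs),
        "LRE": float(np.sum(r * j ** 2) / n_runs),
        "GLN": float(np.sum(r.sum(axis=1) ** 2) / n_runs),
        "RLN": float(np.sum(r.sum(axis=0) ** 2) / n_runs),
        "RP": float(n_runs / n_pix),
        "LGLRE": float(np.sum(r / i ** 2) / n_runs),
        "HGLRE": float(np.sum(r * i ** 2) / n_runs),
        "SRLGLE": float(np.sum(r / (i ** 2 * j ** 2)) / n_runs),
        "SRHGLE": float(np.sum(r * i ** 2 / j ** 2) / n_runs),
        "LRLGLE": float(np.sum(r * j ** 2 / i ** 2) / n_runs),
        "LRHGLE": float(np.sum(r * i ** 2 * j ** 2) / n_runs),
    }
    return {prefix + k: vals[k] for k in _GLRLM_NAMES}


def _tumour_core(roi_mask: np.ndarray) -> np.ndarray:
    """Innermost ~50% of the ROI area by iterative 1-px erosion."""
    target = 0.5 * roi_mask.sum()
    core = roi_mask.copy()
    struct = disk(1)
    while core.sum() > target:
        eroded = binary_erosion(core, structure=struct)
        if not eroded.any():
            break  # thin ROI: keep the last non-empty core
        core = eroded
        if core.sum() <= target:
            return core
    return core


def vascular_features(vessel: VesselMask, roi: ROIMask,
                      fit: ReplenishmentFit) -> dict[str, float]:
    """The 15 morphological/functional vascular features.

    Distances are Euclidean distances of non-vessel ROI pixels to the
    nearest vessel pixel.  With no vessels the distance map falls back to
    the distance to the ROI boundary (the maximum feasible distance), and
    the periphery/core rBV ratio uses a floored core rBV of one pixel per
    core area as a finite sentinel.
    """
    roi_mask = roi.mask
    v = vessel.mask & roi_mask
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")

    lab, n_comp = label(v, connectivity=2, return_num=True)
    sizes = np.bincount(lab.ravel())[1:] if n_comp else np.array([])

    skel = skeletonize(v)
    network_length = int(skel.sum())
    neigh = convolve(skel.astype(np.int64), np.ones((3, 3), dtype=np.int64),
                     mode="constant") - skel
    n_branch = int(np.sum(skel & (neigh >= 3)))

    if v.any():
        dist = distance_transform_edt(~v)
    else:
        dist = distance_transform_edt(roi_mask)  # distance to ROI boundary
    dvals = dist[roi_mask & ~v]
    if dvals.size == 0:  # vessel mask covers the whole ROI
        dvals = np.zeros(1)

    core = _tumour_core(roi_mask)
    periph = roi_mask & ~core
    n_core, n_periph = int(core.sum()), int(periph.sum())
    rbv = v.sum() / n_roi
    rbv_core = (v & core).sum() / n_core if n_core else 0.0
    rbv_periph = (v & periph).sum() / n_periph if n_periph else 0.0
    if rbv_core > 0:
        ratio = rbv_periph / rbv_core
    else:
        # finite sentinel: as if a single core pixel were vessel
        ratio = rbv_periph / (1.0 / max(n_core, 1))

    return {
        "vasc_n_vessels": float(n_comp),
        "vasc_mean_vessel_size": float(sizes.mean()) if n_comp else 0.0,
        "vasc_median_vessel_size": float(np.median(sizes)) if n_comp else 0.0,
        "vasc_network_length": float(network_length),
        "vasc_dist_mean": float(dvals.mean()),
        "vasc_dist_std": float(dvals.std()),
        "vasc_dist_max": float(dvals.max()),
        "vasc_rbv": float(rbv),
        "vasc_rbv_periphery_core_ratio": float(ratio),
        "vasc_flow_velocity": float(fit.velocity),
        "vasc_vascular_area": float(v.sum()),
        "vasc_max_vessel_size": float(sizes.max()) if n_comp else 0.0,
        "vasc_n_branch_points": float(n_branch),
        "vasc_rbv_periphery": float(rbv_periph),
        "vasc_rbv_core": float(rbv_core),
    }


def swt_subbands(image: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Level-1 undecimated (stationary) wavelet subbands A/H/V/D, input-sized."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    ph, pw = h + (h % 2), w + (w % 2)  # swt needs even extents
    padded = np.pad(image, ((0, ph - h), (0, pw - w)), mode="symmetric")
    (ca, (ch, cv, cd)), = pywt.swt2(padded, wavelet, level=1)
    return {"A": ca[:h, :w], "H": ch[:h, :w], "V": cv[:h, :w], "D": cd[:h, :w]}


def wavelet_features(image: np.ndarray, roi: ROIMask,
                     q: QuantizationParams | None = None,
                     wavelet: str = "coif1") -> dict[str, float]:
    """The 176 wavelet features: 44 intensity+texture features per subband."""
    if q is None:
        q = QuantizationParams()
    out: dict[str, float] = {}
    for sb, img in swt_subbands(image, wavelet).items():
        out.update({f"wav{sb}_{k}": v
                    for k, v in first_order_features(img, roi, q).items()})
        out.update(glcm_features(img, roi, q, prefix=f"wav{sb}_glcm_"))
        out.update(glrlm_features(img, roi, q, prefix=f"wav{sb}_glrlm_"))
    return out


@dataclass(frozen=True)
class ExtractionParams:
    """End-to-end extraction parameters."""

    quantization: QuantizationParams = field(default_factory=QuantizationParams)
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    wavelet: str = "coif1"
    beam_width: float = 1.0
    mad_k: float = 3.0
    threshold_window: int = 15
    min_speckle_size: int = 5


@dataclass
class FeatureVector:
    """One scan's 235 named features plus scan metadata."""

    values: dict[str, float]
    scan_id: str = ""
    mouse_id: str = ""
    model_label: str = ""
    position_id: str = ""
    user_id: str = ""
    dataset_id: int = 0

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        if missing:
            raise ValueError(f"missing features: {missing[:5]}...")
        if len(self.values) != len(FEATURE_NAMES):
            raise ValueError("unexpected extra features")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features: {bad}")
        # canonical order
        self.values = {n: float(self.values[n]) for n in FEATURE_NAMES}


def reference_image(seq: CEUSSequence, params: ExtractionParams,
                    excluded: frozenset[int] | None = None) -> np.ndarray:
    """Temporal mean of the denoised pre-destruction frames."""
    if excluded is None:
        excluded = detect_artifact_frames(seq, mad_k=params.mad_k)
    idx = [t for t in range(seq.destruction_frame) if t not in excluded]
    if not idx:
        raise ValueError("no usable pre-destruction frames")
    den = [denoise_frame(seq.frames[t], params.denoise) for t in idx]
    return np.mean(den, axis=0)


def extract_all(seq: CEUSSequence, roi: ROIMask,
                params: ExtractionParams | None = None,
                user_id: str = "", dataset_id: int = 0,
                _reference: np.ndarray | None = None,
                _excluded: frozenset[int] | None = None) -> FeatureVector:
    """Compute the full 235-feature vector for one scan and one ROI.

    ``_reference``/``_excluded`` allow a study driver to reuse the
    ROI-independent denoised reference image and artifact set across the
    observers of the same scan.
    """
    if params is None:
        params = ExtractionParams()
    excluded = _excluded if _excluded is not None else detect_artifact_frames(
        seq, mad_k=params.mad_k)
    ref = _reference if _reference is not None else reference_image(seq, params, excluded)

    values: dict[str, float] = {}
    values.update(first_order_features(ref, roi, params.quantization))
    values.update(glcm_features(ref, roi, params.quantization))
    values.update(glrlm_features(ref, roi, params.quantization))

    vessel = segment_vessels(seq, roi, mad_k=params.mad_k,
                             window=params.threshold_window,
                             min_size=params.min_speckle_size)
    fit = fit_replenishment(seq, roi, excluded, beam_width=params.beam_width)
    values.update(vascular_features(vessel, roi, fit))
    values.update(wavelet_features(ref, roi, params.quantization, params.wavelet))

    return FeatureVector(values=values, scan_id=seq.scan_id, mouse_id=seq.mouse_id,
                         model_label=seq.model_label, position_id=seq.position_id,
                         user_id=user_id, dataset_id=dataset_id)


METADATA_COLUMNS = ["scan_id", "mouse_id", "model_label", "position_id",
                    "user_id", "dataset"]


def extract_study(study: Study, params: ExtractionParams | None = None,
                  progress: bool = False):
    """Extract features for every (scan, observer) pair of a study.

    Returns a :class:`pandas.DataFrame` with one row per (scan, user):
    metadata columns followed by the 235 feature columns in canonical
    order.
    """
    import pandas as pd

    if params is None:
        params = ExtractionParams()
    rows = []
    scans: list[ScanRecord] = study.scans
    for k, rec in enumerate(scans):
        seq = rec.seq
        excluded = detect_artifact_frames(seq, mad_k=params.mad_k)
        ref = reference_image(seq, params, excluded)
        for roi in rec.rois:
            fv = extract_all(seq, roi, params, user_id=roi.user_id,
                             dataset_id=rec.dataset, _reference=ref,
                             _excluded=excluded)
            row = dict(scan_id=fv.scan_id, mouse_id=fv.mouse_id,
                       model_label=fv.model_label, position_id=fv.position_id,
                       user_id=fv.user_id, dataset=fv.dataset_id)
            row.update(fv.values)
            rows.append(row)
        if progress:
            print(f"extracted {k + 1}/{len(scans)} scans", flush=True)
    return pd.DataFrame(rows, columns=METADATA_COLUMNS + FEATURE_NAMES)
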