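"""Tumor-candidate feature battery, mRMR selection and TP/FP classification.

Each connected tumor candidate yields a fixed battery of 157 named features
spanning size, shape, enhancement and 3D texture, computed on the candidate
region and on a peri-tumoral "edge" shell (a 2-voxel outer rim inside the
liver, capturing healthy-tissue enhancement around the lesion):

* size/shape (4): volume (ml), maximal 3D diameter (mm), tumor size ratio
  (candidate / liver volume) and binary elongation (candidate volume over
  its bounding-box volume; pi/6 for a perfect sphere);
* intensity statistics (24): mean, std, min, max, median, five percentiles,
  skewness and kurtosis for the tumor region and the edge shell;
* enhancement (3): edge-tumor mean contrast plus mean and max blobness of
  the candidate from the Hessian dark-blob map;
* 3D gray-level co-occurrence texture (126): cluster prominence, cluster
  shade, correlation, energy, entropy, inertia and inverse difference, per
  region, at 3 gray-level quantizations (8/16/32) and 3 offset distances
  (1/2/3 voxels), direction-averaged over the 13 unique 3D offsets.

mRMR selection greedily maximizes mutual information with the TP/FP label
minus mean redundancy to already-selected features, on equal-frequency
8-bin discretizations; classification is a margin (SVM) classifier on the
standardized selected features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from sklearn.metrics import mutual_info_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import Mask, Volume

GLCM_STATS = ("cluster_prominence", "cluster_shade", "correlation", "energy",
              "entropy", "inertia", "inverse_difference")
INTENSITY_STATS = ("mean", "std", "min", "max", "median", "p5", "p10", "p25",
                   "p75", "p90", "skewness", "kurtosis")
QUANTIZATIONS = (8, 16, 32)
DISTANCES = (1, 2, 3)
REGIONS = ("tumor", "edge")
MIN_TEXTURE_VOXELS = 8
EDGE_SHELL_VOXELS = 2


def feature_manifest() -> pd.DataFrame:
    """Names, categories and parameters of the full 157-feature battery."""
    rows = []

    def add(name, descriptor, **params):
        rows.append({"name": name, "descriptor": descriptor, **params})

    add("tumor_volume_ml", "Size")
    add("tumor_max_diameter_mm", "Size")
    add("tumor_size_ratio", "Shape")
    add("tumor_binary_elongation", "Shape")
    for region in REGIONS:
        for stat in INTENSITY_STATS:
            add(f"{region}_intensity_{stat}",
                "Enhancement" if region == "edge" else "Shape",
                region=region, stat=stat)
    add("edge_tumor_contrast", "Enhancement")
    add("tumor_blobness_mean", "Texture")
    add("tumor_blobness_max", "Texture")
    for region in REGIONS:
        for q in QUANTIZATIONS:
            for d in DISTANCES:
                for stat in GLCM_STATS:
                    add(f"{region}_glcm_q{q}_d{d}_{stat}", "Texture",
                        region=region, quantization=q, distance=d, stat=stat)
    df = pd.DataFrame(rows)
    assert len(df) == 157, f"manifest defines {len(df)} features, expected 157"
    return df


FEATURE_NAMES: list[str] = list(feature_manifest()["name"])


@dataclass
class TumorCandidate:
    """A connected lesion hypothesis with its feature vector and label."""

    component_id: int
    voxels: np.ndarray               # (n, 3) integer indices
    volume_ml: float
    diameter_mm: float
    features: pd.Series | None = None
    label: str = "unknown"           # TP / FP / unknown


def extract_candidates(tumor_mask: Mask, min_volume_ml: float = 0.0
                       ) -> list[TumorCandidate]:
    """26-connected components of the tumor mask, filtered by minimum volume."""
    struct = ndi.generate_binary_structure(3, 3)
    lab, n = ndi.label(tumor_mask.binary(), structure=struct)
    vox_ml = float(np.prod(tumor_mask.spacing)) / 1000.0
    out = []
    for k in range(1, n + 1):
        vox = np.argwhere(lab == k)
        vol = len(vox) * vox_ml
        if vol < min_volume_ml:
            continue
        out.append(TumorCandidate(component_id=k, voxels=vox, volume_ml=vol,
                                  diameter_mm=_max_diameter(vox, tumor_mask.spacing)))
    return out


def _max_diameter(vox: np.ndarray, spacing, max_points: int = 400) -> float:
    pts = (vox + 0.5) * np.asarray(spacing)
    if len(pts) > max_points:   # deterministic thinning for big components
        pts = pts[:: len(pts) // max_points + 1]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# 3D gray-level co-occurrence
# ---------------------------------------------------------------------------

_GLCM_OFFSETS = [(dx, dy, dz)
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                 if (dx, dy, dz) > (0, 0, 0)]   # 13 unique 3D directions


def quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of region intensities to ``levels`` levels."""
    v = np.asarray(values, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.zeros(v.shape, dtype=np.intp)
    q = np.floor((v - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def cooccurrence_matrix(quantized: np.ndarray, region: np.ndarray,
                        levels: int, distance: int = 1,
                        offsets=None) -> np.ndarray:
    """Symmetric, normalized 3D co-occurrence matrix over a region mask.

    Pairs are counted for every offset (scaled by ``distance``) whose both
    endpoints lie inside the region, accumulated over all offsets and
    symmetrized.
    """
    offsets = offsets or _GLCM_OFFSETS
    P = np.zeros((levels, levels), dtype=np.float64)
    reg = np.asarray(region).astype(bool)
    q = np.asarray(quantized)
    for off in offsets:
        off = tuple(int(o) * distance for o in off)
        sl_a = tuple(slice(None, -o) if o > 0 else slice(-o, None) if o < 0
                     else slice(None) for o in off)
        sl_b = tuple(slice(o, None) if o > 0 else slice(None, o) if o < 0
                     else slice(None) for o in off)
        valid = reg[sl_a] & reg[sl_b]
        if not valid.any():
            continue
        a = q[sl_a][valid]
        b = q[sl_b][valid]
        np.add.at(P, (a, b), 1.0)
        np.add.at(P, (b, a), 1.0)
    total = P.sum()
    return P / total if total > 0 else P


def glcm_statistics(P: np.ndarray) -> dict[str, float]:
    """The seven co-occurrence statistics of the feature battery.

    For a uniform region (single gray level) energy is 1 and entropy and
    inertia are 0; correlation is defined as 0 when either marginal has zero
    variance.
    """
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    if P.sum() == 0:
        return {s: 0.0 for s in GLCM_STATS}
    mu_i = float((ii * P).sum())
    mu_j = float((jj * P).sum())
    var_i = float(((ii - mu_i) ** 2 * P).sum())
    var_j = float(((jj - mu_j) ** 2 * P).sum())
    dev = ii + jj - mu_i - mu_j
    nz = P > 0
    stats = {
        "cluster_prominence": float((dev**4 * P).sum()),
        "cluster_shade": float((dev**3 * P).sum()),
        "correlation": (float((((ii - mu_i) * (jj - mu_j) * P).sum())
                              / np.sqrt(var_i * var_j))
                        if var_i > 0 and var_j > 0 else 0.0),
        "energy": float((P**2).sum()),
        "entropy": float(-(P[nz] * np.log2(P[nz])).sum()),
        "inertia": float((((ii - jj) ** 2) * P).sum()),
        "inverse_difference": float((P / (1.0 + np.abs(ii - jj))).sum()),
    }
    return stats


def edge_shell(candidate_mask: np.ndarray, liver: np.ndarray,
               width: int = EDGE_SHELL_VOXELS) -> np.ndarray:
    """Peri-tumoral rim: ``width``-voxel outer shell of the candidate, inside
    the liver and outside the candidate itself."""
    dil = ndi.binary_dilation(candidate_mask, iterations=width)
    return dil & ~candidate_mask & np.asarray(liver).astype(bool)


def _intensity_stats(vals: np.ndarray) -> dict[str, float]:
    if vals.size == 0:
        return {s: 0.0 for s in INTENSITY_STATS}
    out = {
        "mean": float(vals.mean()), "std": float(vals.std()),
        "min": float(vals.min()), "max": float(vals.max()),
        "median": float(np.median(vals)),
        "p5": float(np.percentile(vals, 5)), "p10": float(np.percentile(vals, 10)),
        "p25": float(np.percentile(vals, 25)), "p75": float(np.percentile(vals, 75)),
        "p90": float(np.percentile(vals, 90)),
    }
    if vals.size > 2 and vals.std() > 0:
        out["skewness"] = float(sps.skew(vals))
        out["kurtosis"] = float(sps.kurtosis(vals))
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    return out


def compute_features(candidate: TumorCandidate, volume: Volume,
                     liver: Mask | np.ndarray,
                     blob_map: np.ndarray | None = None) -> pd.Series:
    """The full 157-feature vector of one candidate (see module docstring).

    Candidates below the co-occurrence minimum (8 voxels) get imputed (zero)
    texture features, flagged via the ``texture_imputed`` attribute.
    """
    liv = liver.binary() if isinstance(liver, Mask) else np.asarray(liver).astype(bool)
    shape = volume.data.shape
    cmask = np.zeros(shape, dtype=bool)
    cmask[tuple(candidate.voxels.T)] = True
    shell = edge_shell(cmask, liv)

    feats: dict[str, float] = {}
    feats["tumor_volume_ml"] = candidate.volume_ml
    feats["tumor_max_diameter_mm"] = candidate.diameter_mm
    liver_vol = float(liv.sum()) * float(np.prod(volume.spacing)) / 1000.0
    feats["tumor_size_ratio"] = candidate.volume_ml / liver_vol if liver_vol else 0.0
    ext = candidate.voxels.max(axis=0) - candidate.voxels.min(axis=0) + 1
    feats["tumor_binary_elongation"] = float(len(candidate.voxels) / np.prod(ext))

    tvals = volume.data[cmask]
    evals = volume.data[shell]
    for region, vals in (("tumor", tvals), ("edge", evals)):
        for stat, val in _intensity_stats(vals).items():
            feats[f"{region}_intensity_{stat}"] = val
    feats["edge_tumor_contrast"] = (float(evals.mean() - tvals.mean())
                                    if evals.size else 0.0)
    if blob_map is not None:
        bvals = np.asarray(blob_map)[cmask]
        feats["tumor_blobness_mean"] = float(bvals.mean())
        feats["tumor_blobness_max"] = float(bvals.max())
    else:
        feats["tumor_blobness_mean"] = 0.0
        feats["tumor_blobness_max"] = 0.0

    texture_imputed = False
    for region, rmask, vals in (("tumor", cmask, tvals), ("edge", shell, evals)):
        ok = vals.size >= MIN_TEXTURE_VOXELS
        if not ok:
            texture_imputed = True
        qcache = {}
        for q in QUANTIZATIONS:
            if ok:
                full = np.zeros(shape, dtype=np.intp)
                full[rmask] = quantize(vals, q)
                qcache[q] = full
            for d in DISTANCES:
                if ok:
                    P = cooccurrence_matrix(qcache[q], rmask, q, distance=d)
                    stats = glcm_statistics(P)
                else:
                    stats = {s: 0.0 for s in GLCM_STATS}
                for s in GLCM_STATS:
                    feats[f"{region}_glcm_q{q}_d{d}_{s}"] = stats[s]

    series = pd.Series([feats[n] for n in FEATURE_NAMES], index=FEATURE_NAMES,
                       dtype=float)
    series.attrs["texture_imputed"] = texture_imputed
    candidate.features = series
    return series


# ---------------------------------------------------------------------------
# mRMR selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureSelection:
    selected: list[str]
    relevance: list[float]        # MI with the label, per step
    redundancy: list[float]       # mean MI to already-selected, per step


def discretize_equal_frequency(x: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Quantile binning; ties collapse bins, constant columns give one bin."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x, side="right")


def mrmr_select(features: pd.DataFrame | np.ndarray, labels, k: int,
                n_bins: int = 8) -> FeatureSelection:
    """Greedy minimum-redundancy maximum-relevance feature selection.

    Step 1 takes the feature with maximal mutual information with the label;
    each later step maximizes relevance minus mean redundancy to the already
    selected set.  Mutual information is computed on equal-frequency
    discretizations; ties break by manifest (column) order.  Constant
    columns are excluded with a warning.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two label classes")
    if not (1 <= k <= X.shape[1]):
        raise ValueError("k out of range")

    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = X.shape[1] - len(keep)
    if dropped:
        warnings.warn(f"excluding {dropped} constant feature column(s)")
    disc = {j: discretize_equal_frequency(X[:, j], n_bins) for j in keep}
    relevance = {j: mutual_info_score(y, disc[j]) for j in keep}

    selected: list[int] = []
    rel_log, red_log = [], []
    mi_cache: dict[tuple[int, int], float] = {}

    def mi_ff(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mi_cache:
            mi_cache[key] = mutual_info_score(disc[a], disc[b])
        return mi_cache[key]

    for _ in range(min(k, len(keep))):
        best_j, best_score, best_red = None, -np.inf, 0.0
        for j in keep:
            if j in selected:
                continue
            red = (np.mean([mi_ff(j, s) for s in selected]) if selected else 0.0)
            score = relevance[j] - red
            if score > best_score + 1e-15:
                best_j, best_score, best_red = j, score, red
        selected.append(best_j)
        rel_log.append(relevance[best_j])
        red_log.append(best_red)
    return FeatureSelection(selected=[names[j] for j in selected],
                            relevance=rel_log, redundancy=red_log)


# ---------------------------------------------------------------------------
# TP/FP classification
# ---------------------------------------------------------------------------

def classify_candidates(selection: FeatureSelection,
                        train_features: pd.DataFrame, train_labels,
                        test_features: pd.DataFrame,
                        classifier=None):
    """Margin classifier (standardized SVM by default) on selected features.

    Returns (predicted labels, decision scores) for the test candidates.
    """
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    cols = selection.selected
    clf = classifier or make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    clf.fit(train_features[cols].to_numpy(), y)
    Xt = test_features[cols].to_numpy()
    pred = clf.predict(Xt)
    if hasattr(clf, "decision_function"):
        scores = clf.decision_function(Xt)
    else:  # pragma: no cover
        scores = clf.predict_proba(Xt)[:, 1]
    return pred, scores
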