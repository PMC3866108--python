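"""kNN posterior estimation, class-imbalance weight correction, and
assembly of probabilistic segmentations.

The classifier assigns each voxel a posterior probability for each tissue
type and background as the fraction of its k nearest training voxels (k=50
by default, Euclidean distance in standardized feature space) that carry
each label.  Because tissue classes differ enormously in size (myelinated
white matter is a ~1% minority), an optional local correction multiplies
each posterior by a class weight

    w_i = (Num(C_i) / min_j Num(C_j)) ** (-1 / exponent),   exponent > 1,

where Num(C_i) counts class-i members among the sample's N nearest
neighbours (N = k by default; a global variant counts over the whole
training set).  The rarest class present gets weight exactly 1 and larger
classes are discounted; as the exponent grows all weights approach 1 and
the correction vanishes.  Corrected posteriors are renormalized to sum to
1, which leaves the majority class unchanged.

Neighbour ties at the k-th distance are resolved by including the tied
training rows with the smallest indices until exactly k are kept; this
makes the posteriors deterministic and lets an exhaustive distance-matrix
oracle reproduce them exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import KDTree

from neoseg.imaging import LabelMap, ProbMaps, TissueLabel, VolumeImage
from neoseg.preprocess import ScalingParams, apply_scaling, fit_scaling
from neoseg.features import FEATURE_COLUMNS, LABEL_COLUMN, extract_features
from neoseg.register import AffineTransform

DEFAULT_K = 50
_TIE_RTOL = 1e-9
_QUERY_CHUNK = 100_000


@dataclass
class KnnModel:
    """Trained voxel classifier: standardized training matrix + labels."""

    features: np.ndarray        # (n_train, n_features), standardized
    labels: np.ndarray          # (n_train,), TissueLabel codes
    k: int
    scaling: ScalingParams
    class_codes: np.ndarray     # codes the posterior vector is indexed by

    def __post_init__(self) -> None:
        self.features = np.ascontiguousarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if not 1 <= self.k <= len(self.features):
            raise ValueError(f"k={self.k} outside [1, n_train={len(self.features)}]")
        if len(self.labels) != len(self.features):
            raise ValueError("labels/features length mismatch")
        if not np.isin(self.labels, TissueLabel.codes()).all():
            raise ValueError("invalid tissue codes in training labels")
        self.class_codes = np.asarray(self.class_codes, dtype=np.int16)
        self._tree: KDTree | None = None
        # training-set class counts, for the 'global' weighting variant
        self.global_counts = np.array(
            [(self.labels == c).sum() for c in self.class_codes], dtype=np.int64
        )

    @property
    def tree(self) -> KDTree:
        if self._tree is None:
            self._tree = KDTree(self.features)
        return self._tree

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.save(out_dir / "train_features.npy", self.features)
        np.save(out_dir / "train_labels.npy", self.labels)
        meta = {
            "k": self.k,
            "class_codes": self.class_codes.tolist(),
            "scaling_mean": self.scaling.mean.to_dict(),
            "scaling_std": self.scaling.std.to_dict(),
        }
        (out_dir / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir) -> "KnnModel":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "model.json").read_text())
        scaling = ScalingParams(
            mean=pd.Series(meta["scaling_mean"]), std=pd.Series(meta["scaling_std"])
        )
        return cls(
            features=np.load(in_dir / "train_features.npy"),
            labels=np.load(in_dir / "train_labels.npy"),
            k=meta["k"],
            scaling=scaling,
            class_codes=np.array(meta["class_codes"], dtype=np.int16),
        )


def train_model(
    training_table: pd.DataFrame,
    k: int = DEFAULT_K,
    class_codes: np.ndarray | None = None,
) -> KnnModel:
    """Fit feature scaling on the training table and build the kNN model."""
    if LABEL_COLUMN not in training_table.columns:
        raise ValueError("training table has no label column")
    scaling = fit_scaling(training_table, FEATURE_COLUMNS)
    scaled = apply_scaling(training_table, scaling)
    if class_codes is None:
        class_codes = TissueLabel.codes()
    return KnnModel(
        features=scaled[FEATURE_COLUMNS].to_numpy(),
        labels=training_table[LABEL_COLUMN].to_numpy(),
        k=k,
        scaling=scaling,
        class_codes=class_codes,
    )


def _brute_rows(model: KnnModel, xq: np.ndarray) -> np.ndarray:
    """Deterministic k-nearest indices for query rows by full distance sort.

    Ordering key is (distance, training index): ties at the k-th distance
    admit the smallest-index rows, matching the documented tie rule.
    """
    d2 = ((model.features[None, :, :] - xq[:, None, :]) ** 2).sum(axis=2)
    n = model.features.shape[0]
    out = np.empty((len(xq), model.k), dtype=np.int64)
    idx = np.arange(n)
    for r in range(len(xq)):
        order = np.lexsort((idx, d2[r]))
        out[r] = order[: model.k]
    return out


def neighbor_class_counts(model: KnnModel, query_features: np.ndarray) -> np.ndarray:
    """Count each class among the k nearest training rows of every query row.

    Returns an (n_query, n_classes) integer matrix aligned with
    ``model.class_codes``; each row sums to k.
    """
    xq = np.ascontiguousarray(query_features, dtype=np.float64)
    if xq.ndim != 2 or xq.shape[1] != model.features.shape[1]:
        raise ValueError("query feature dimensionality mismatch")
    n_train = len(model.features)
    k = model.k
    code_to_col = np.full(int(model.class_codes.max()) + 1, -1, dtype=np.int64)
    code_to_col[model.class_codes] = np.arange(len(model.class_codes))
    counts = np.zeros((len(xq), len(model.class_codes)), dtype=np.int64)

    for start in range(0, len(xq), _QUERY_CHUNK):
        chunk = xq[start : start + _QUERY_CHUNK]
        kq = min(k + 1, n_train)
        dist, ind = model.tree.query(chunk, k=kq)
        if n_train > k:
            # A tie straddling the k-th position means the tree's arbitrary
            # ordering might disagree with the smallest-index rule; resolve
            # those rows exhaustively.
            tied = dist[:, k] - dist[:, k - 1] <= _TIE_RTOL * np.maximum(dist[:, k], 1.0)
            ind = ind[:, :k]
            if tied.any():
                ind[tied] = _brute_rows(model, chunk[tied])
        labels = model.labels[ind]  # (chunk, k)
        cols = code_to_col[labels]
        rows = np.repeat(np.arange(len(chunk)), labels.shape[1])
        np.add.at(counts[start : start + _QUERY_CHUNK], (rows, cols.ravel()), 1)
    return counts


def knn_posteriors(model: KnnModel, query: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Posterior probability per class for each query row: (class count among
    the k nearest training rows) / k.  Rows sum to 1 exactly.

    ``query`` must already be standardized with the model's scaling
    parameters; a gross scale mismatch with the stored training statistics
    is rejected.
    """
    if isinstance(query, pd.DataFrame):
        xq = query[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    else:
        xq = np.asarray(query, dtype=np.float64)
    if xq.size and np.abs(xq).max() > 1e3:
        raise ValueError(
            "query features look unstandardized (|value| > 1e3 in standardized space); "
            "apply the model's ScalingParams first"
        )
    counts = neighbor_class_counts(model, xq)
    return counts / float(model.k)


@dataclass
class ClassWeights:
    """Per-class imbalance weights; the rarest present class has weight 1."""

    weights: dict[int, float]
    exponent: float
    neighborhood_size: int

    def as_vector(self, class_codes: np.ndarray) -> np.ndarray:
        return np.array([self.weights.get(int(c), 0.0) for c in class_codes])


def class_weights(neighbor_labels, exponent: float) -> ClassWeights:
    """Imbalance weights from a multiset of neighbour labels.

    w_i = (Num(C_i)/min_j Num(C_j))**(-1/exponent) over the classes present;
    absent classes get no weight (their posterior is already zero).
    """
    if exponent <= 1:
        raise ValueError(f"exponent must be > 1, got {exponent}")
    labels = np.asarray(list(neighbor_labels))
    if labels.size == 0:
        raise ValueError("neighbor label multiset is empty")
    codes, counts = np.unique(labels, return_counts=True)
    m = counts.min()
    w = (counts / m) ** (-1.0 / exponent)
    return ClassWeights(
        weights={int(c): float(wi) for c, wi in zip(codes, w)},
        exponent=float(exponent),
        neighborhood_size=int(labels.size),
    )


def corrected_posteriors(raw: np.ndarray, w: ClassWeights, class_codes: np.ndarray) -> np.ndarray:
    """Multiply posteriors by class weights, then renormalize to sum to 1.

    Renormalization does not change the majority class; it restores the
    probability-map invariant after the weighting.
    """
    raw = np.asarray(raw, dtype=float)
    wv = w.as_vector(np.asarray(class_codes))
    prod = raw * wv
    s = prod.sum()
    if s <= 0:
        warnings.warn("all weighted posteriors are zero; returning raw posteriors")
        return raw.copy()
    return prod / s


def _weighted_counts_to_posteriors(
    counts: np.ndarray, exponent: float | None, global_counts: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized posterior computation for a count matrix, optionally with
    the imbalance correction (local neighbourhood counts by default, global
    training-set counts when ``global_counts`` is given)."""
    k = counts.sum(axis=1, keepdims=True).astype(float)
    raw = counts / k
    if exponent is None:
        return raw
    if exponent <= 1:
        raise ValueError(f"exponent must be > 1, got {exponent}")
    base = global_counts[None, :].astype(float) if global_counts is not None else counts.astype(float)
    masked = np.where(base > 0, base, np.inf)
    m = masked.min(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        w = np.where(base > 0, (base / m) ** (-1.0 / exponent), 0.0)
    prod = raw * w
    s = prod.sum(axis=1, keepdims=True)
    bad = (s <= 0).ravel()
    if bad.any():
        warnings.warn("weighted posteriors vanished for some voxels; raw kept there")
        prod[bad] = raw[bad]
        s[bad] = 1.0
    return prod / s


def native_neighbor_counts(
    model: KnnModel,
    t1: VolumeImage,
    t2: VolumeImage,
    mask: np.ndarray,
    to_atlas: AffineTransform,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Neighbour class counts for every masked native voxel, plus the voxel
    indices; lets callers derive posteriors under several weightings from a
    single (expensive) neighbour search."""
    table = extract_features(t1, t2, mask, to_atlas)
    scaled = apply_scaling(table, model.scaling)
    counts = neighbor_class_counts(model, scaled[FEATURE_COLUMNS].to_numpy())
    ijk = (table["i"].to_numpy(), table["j"].to_numpy(), table["k"].to_numpy())
    return counts, ijk


def probmaps_from_counts(
    counts: np.ndarray,
    ijk: tuple[np.ndarray, np.ndarray, np.ndarray],
    shape: tuple[int, int, int],
    affine: np.ndarray,
    mask: np.ndarray,
    class_codes: np.ndarray,
    weighting: float | None = None,
    global_counts: np.ndarray | None = None,
) -> ProbMaps:
    """Assemble posterior probability maps on the native grid from neighbour
    class counts (optionally imbalance-weighted)."""
    post = _weighted_counts_to_posteriors(counts, weighting, global_counts)
    probs = np.zeros((len(class_codes),) + tuple(shape), dtype=np.float32)
    ii, jj, kk = ijk
    for ci in range(len(class_codes)):
        probs[ci, ii, jj, kk] = post[:, ci]
    return ProbMaps(probs=probs, mask=np.asarray(mask, dtype=bool),
                    affine=np.asarray(affine, dtype=float).copy(), class_codes=class_codes)


def segment_subject(
    model: KnnModel,
    t1: VolumeImage,
    t2: VolumeImage,
    mask: np.ndarray,
    to_atlas: AffineTransform,
    weighting: float | None = None,
    weighting_scope: str = "local",
    classify_space: str = "native",
    atlas_geometry: VolumeImage | None = None,
) -> ProbMaps:
    """Probabilistic segmentation of one subject, in native space.

    In the default ``native`` mode each native-grid voxel is classified
    directly, using its atlas-mapped world position as the spatial feature;
    no probability resampling is needed.  In ``atlas`` mode the atlas grid
    is classified instead and the per-class probability maps are mapped
    back to the native grid through the inverse transform with linear
    interpolation (the flow a registration-based pipeline would use);
    ``atlas_geometry`` must then be given.

    ``weighting`` is the imbalance-correction exponent (> 1) or None for
    plain kNN posteriors.
    """
    from neoseg.register import invert, resample  # local import to avoid cycle

    mask = np.asarray(mask, dtype=bool)
    if classify_space not in ("native", "atlas"):
        raise ValueError("classify_space must be 'native' or 'atlas'")
    codes = model.class_codes
    if not mask.any():
        probs = np.zeros((len(codes),) + t1.shape, dtype=np.float32)
        return ProbMaps(probs=probs, mask=mask, affine=t1.affine.copy(), class_codes=codes)

    gcounts = model.global_counts if weighting_scope == "global" else None

    if classify_space == "native":
        counts, ijk = native_neighbor_counts(model, t1, t2, mask, to_atlas)
        return probmaps_from_counts(
            counts, ijk, t1.shape, t1.affine, mask, codes, weighting, gcounts
        )

    # atlas mode: resample images and mask onto the atlas grid, classify
    # there with identity spatial mapping, then pull probabilities back.
    if atlas_geometry is None:
        raise ValueError("classify_space='atlas' requires atlas_geometry")
    # ``to_atlas`` maps subject world -> atlas world; resampling onto the
    # atlas grid needs the opposite direction.
    from_atlas = invert(to_atlas)
    subj_to_atlas = to_atlas
    t1_a = resample(t1, from_atlas, atlas_geometry, "linear")
    t2_a = resample(t2, from_atlas, atlas_geometry, "linear")
    mask_img = VolumeImage(data=mask.astype(np.float32), affine=t1.affine.copy())
    mask_a = np.asarray(resample(mask_img, from_atlas, atlas_geometry, "nearest").data) > 0.5
    table = extract_features(t1_a, t2_a, mask_a, AffineTransform.identity())
    scaled = apply_scaling(table, model.scaling)
    counts = neighbor_class_counts(model, scaled[FEATURE_COLUMNS].to_numpy())
    post = _weighted_counts_to_posteriors(counts, weighting, gcounts)
    probs_native = np.zeros((len(codes),) + t1.shape, dtype=np.float32)
    ii, jj, kk = table["i"].to_numpy(), table["j"].to_numpy(), table["k"].to_numpy()
    for ci in range(len(codes)):
        atlas_map = np.zeros(atlas_geometry.shape, dtype=np.float32)
        atlas_map[ii, jj, kk] = post[:, ci]
        native = resample(
            VolumeImage(data=atlas_map, affine=atlas_geometry.affine.copy()),
            subj_to_atlas,
            t1,
            "linear",
        )
        probs_native[ci] = native.data
    # renormalize after interpolation and restrict to the native mask
    s = probs_native.sum(axis=0)
    ok = mask & (s > 0)
    probs_native[:, ok] /= s[ok]
    probs_native[:, ~mask] = 0.0
    # voxels inside the mask that mapped outside the atlas field of view:
    # fall back to background
    missing = mask & (s <= 0)
    if missing.any():
        bg_col = int(np.flatnonzero(codes == TissueLabel.BG)[0])
        probs_native[bg_col, missing] = 1.0
    return ProbMaps(probs=probs_native, mask=mask, affine=t1.affine.copy(), class_codes=codes)
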