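"""Per-voxel feature tables: two intensities plus three atlas-space
coordinates, with optional training labels.

Each brain voxel contributes one row with its T1 and T2 intensities and its
spatial position expressed in the coordinate system of the average brain
(world mm, not voxel indices, so values are comparable across subjects with
different grids).  Tables are pandas DataFrames; the ``i/j/k`` columns hold
the native voxel index for mapping classifier output back onto the grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from neoseg.imaging import LabelMap, TissueLabel, VolumeImage
from neoseg.register import AffineTransform

FEATURE_COLUMNS = ["t1", "t2", "x_atlas", "y_atlas", "z_atlas"]
INDEX_COLUMNS = ["i", "j", "k"]
LABEL_COLUMN = "label"

DEFAULT_TRAINING_FRACTION = 0.20


def extract_features(
    t1: VolumeImage,
    t2: VolumeImage,
    mask: np.ndarray,
    to_atlas: AffineTransform,
    labels: LabelMap | None = None,
) -> pd.DataFrame:
    """Build the per-voxel feature table for a subject.

    Parameters
    ----------
    to_atlas : AffineTransform
        Maps the subject's native world coordinates into atlas (average
        brain) world coordinates.
    labels : LabelMap, optional
        When given (training subjects), a ``label`` column is appended.

    Returns
    -------
    DataFrame with columns t1, t2, x_atlas, y_atlas, z_atlas, i, j, k and,
    for training subjects, label.
    """
    if not t1.same_geometry(t2):
        raise ValueError("t1/t2 geometry mismatch")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != t1.shape:
        raise ValueError("mask geometry mismatch")
    if labels is not None and not t1.same_geometry(labels):
        raise ValueError("labels geometry mismatch")

    idx = np.argwhere(mask)
    world = t1.world_coordinates(idx)
    atlas_xyz = to_atlas.apply(world)
    table = pd.DataFrame(
        {
            "t1": np.asarray(t1.data[mask], dtype=np.float64),
            "t2": np.asarray(t2.data[mask], dtype=np.float64),
            "x_atlas": atlas_xyz[:, 0],
            "y_atlas": atlas_xyz[:, 1],
            "z_atlas": atlas_xyz[:, 2],
            "i": idx[:, 0],
            "j": idx[:, 1],
            "k": idx[:, 2],
        }
    )
    if labels is not None:
        table[LABEL_COLUMN] = np.asarray(labels.data[mask], dtype=np.int16)
    return table


def subsample_training(
    tables: list[pd.DataFrame],
    fraction: float = DEFAULT_TRAINING_FRACTION,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomly select a fraction of voxels from *each* training subject.

    Sampling is simple random sampling without replacement, per subject
    (``round(fraction * n_subject)`` rows each), after which the samples
    are merged into a single training table.  Reproducible given ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    parts = []
    for si, tab in enumerate(tables):
        n = len(tab)
        if n == 0:
            warnings.warn(f"training table {si} is empty; skipped")
            continue
        take = int(round(fraction * n))
        if fraction == 1.0:
            take = n
        rows = rng.choice(n, size=take, replace=False)
        rows.sort()
        part = tab.iloc[rows].copy()
        part["subject"] = si
        parts.append(part)
    if not parts:
        raise ValueError("all training tables are empty")
    return pd.concat(parts, ignore_index=True)


def fallback_mask(
    t2: VolumeImage,
    labels: LabelMap | None = None,
) -> np.ndarray:
    """Artifact-convention brain mask when none is supplied.

    Training subjects: union of the nonzero labels.  Test subjects: Otsu
    threshold on T2, keep the largest connected component, then binary
    closing.  Real studies would supply a dedicated brain-extraction mask;
    this is a stand-in so the pipeline runs end to end.
    """
    if labels is not None:
        return labels.data != TissueLabel.BG
    thr = threshold_otsu(np.asarray(t2.data, dtype=float))
    fg = t2.data > thr
    lab, n = ndimage.label(fg)
    if n == 0:
        return fg
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = lab == keep
    return ndimage.binary_closing(mask, structure=np.ones((3, 3, 3), dtype=bool))


def background_shell(mask: np.ndarray, thickness: int = 2) -> np.ndarray:
    """Thin shell of non-brain voxels around the mask, used to give the
    background class training samples."""
    mask = np.asarray(mask, dtype=bool)
    dilated = ndimage.binary_dilation(mask, iterations=thickness)
    return dilated & ~mask
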