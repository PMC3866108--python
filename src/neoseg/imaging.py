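"""Core volumetric data types, the 9-label tissue scheme, and NIfTI I/O.

The label scheme covers the eight neonatal cerebral tissue classes —
cortical grey matter (CoGM), central grey matter (CeGM), unmyelinated and
myelinated white matter (UWM, MWM), extracerebral cerebrospinal fluid (CSF),
ventricles (VENT), brainstem (BS) and cerebellum (CB) — plus background
(BG, code 0).  The numeric codes are an artifact convention; only the set of
names is fixed by the tissue scheme.

Volumes use 0-based voxel indexing and RAS+ world coordinates in mm via the
NIfTI affine.  All spatial reasoning elsewhere in the package is in world
millimetres, never in voxel indices, so that subjects with different grids
are comparable.
"""

from __future__ import annotations

import enum
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

PROB_SUM_TOL = 1e-6


class TissueLabel(enum.IntEnum):
    """Tissue classes: 8 cerebral tissues plus background (code 0)."""

    BG = 0
    CoGM = 1
    CeGM = 2
    UWM = 3
    MWM = 4
    CSF = 5
    VENT = 6
    BS = 7
    CB = 8

    @classmethod
    def codes(cls) -> np.ndarray:
        return np.array([m.value for m in cls], dtype=np.int16)

    @classmethod
    def tissue_classes(cls) -> list["TissueLabel"]:
        """The eight tissue classes, excluding background."""
        return [m for m in cls if m is not cls.BG]


N_CLASSES = len(TissueLabel)


class FormatError(ValueError):
    """Raised when a file is unreadable or not a 3D scalar volume."""


@dataclass
class VolumeImage:
    """A 3D scalar grid with voxel spacing and a voxel-index -> world-mm affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensity per voxel (arbitrary units).
    affine : ndarray, shape (4, 4)
        Maps 0-based voxel indices to RAS+ world coordinates in mm.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm per axis (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_geometry(self, other: "VolumeImage | LabelMap", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def world_coordinates(self, voxel_indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to (n, 3) world mm."""
        idx = np.asarray(voxel_indices, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def copy_with(self, data: np.ndarray) -> "VolumeImage":
        if data.shape != self.shape:
            raise ValueError("data shape mismatch")
        return VolumeImage(data=data, affine=self.affine.copy())


@dataclass
class LabelMap:
    """A 3D grid of tissue-label codes sharing geometry with a companion volume."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"label map must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label map contains non-integer values")
            self.data = np.round(self.data).astype(np.int16)
        valid = np.isin(self.data, TissueLabel.codes())
        if not valid.all():
            bad = np.unique(self.data[~valid])
            raise ValueError(f"invalid tissue codes present: {bad.tolist()}")

    shape = VolumeImage.shape
    spacing = VolumeImage.spacing
    voxel_volume_mm3 = VolumeImage.voxel_volume_mm3
    same_geometry = VolumeImage.same_geometry
    world_coordinates = VolumeImage.world_coordinates


@dataclass
class ProbMaps:
    """Per-class posterior probability grids.

    ``probs`` has shape (n_classes, nx, ny, nz) indexed by TissueLabel code.
    Inside ``mask`` the class probabilities sum to 1 (tolerance 1e-6);
    outside the mask all values are 0.  Stored as float32.
    """

    probs: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    class_codes: np.ndarray = field(default_factory=TissueLabel.codes)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        self.class_codes = np.asarray(self.class_codes)
        if self.probs.ndim != 4 or self.probs.shape[0] != len(self.class_codes):
            raise ValueError("probs must be (n_classes, nx, ny, nz)")
        if self.mask.shape != self.probs.shape[1:]:
            raise ValueError("mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[1:]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_geometry(self, other, atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def validate(self) -> None:
        if self.probs.min() < -PROB_SUM_TOL or self.probs.max() > 1 + PROB_SUM_TOL:
            raise ValueError("probabilities outside [0, 1]")
        s = self.probs.sum(axis=0)
        if self.mask.any() and not np.allclose(s[self.mask], 1.0, atol=1e-5):
            raise ValueError("masked probabilities do not sum to 1")
        if (~self.mask).any() and np.abs(s[~self.mask]).max() > PROB_SUM_TOL:
            raise ValueError("nonzero probability outside mask")


# ---------------------------------------------------------------------------
# I/O

def read_volume(path) -> VolumeImage:
    """Read a 3D NIfTI-1 volume.

    Raises
    ------
    FormatError
        If the file is unreadable or not a 3D scalar image.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several exception types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return VolumeImage(data=np.asarray(data, dtype=np.float32), affine=np.asarray(img.affine))


def read_labelmap(path) -> LabelMap:
    """Read a 3D NIfTI-1 label volume (integer tissue codes)."""
    vol = read_volume(path)
    return LabelMap(data=np.round(vol.data).astype(np.int16), affine=vol.affine)


def write_volume(vol: VolumeImage, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    nib.save(img, str(path))


def write_labelmap(lab: LabelMap, path) -> None:
    img = nib.Nifti1Image(np.asarray(lab.data, dtype=np.int16), lab.affine)
    nib.save(img, str(path))


def write_probmaps(p: ProbMaps, out_dir) -> list[Path]:
    """Write one NIfTI per class (named by tissue), plus a JSON sidecar.

    The sidecar records the class codes, geometry and mask volume so the
    probability maps can be reassembled without guessing the label scheme.
    """
    p.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not p.mask.any():
        warnings.warn("writing ProbMaps with an empty mask: all maps are zero")
    written = []
    names = {m.value: m.name for m in TissueLabel}
    for i, code in enumerate(p.class_codes):
        fname = out_dir / f"prob_{names[int(code)]}.nii.gz"
        nib.save(nib.Nifti1Image(p.probs[i].astype(np.float32), p.affine), str(fname))
        written.append(fname)
    mask_file = out_dir / "mask.nii.gz"
    nib.save(nib.Nifti1Image(p.mask.astype(np.uint8), p.affine), str(mask_file))
    sidecar = {
        "classes": {names[int(c)]: int(c) for c in p.class_codes},
        "shape": list(p.shape),
        "affine": np.asarray(p.affine).tolist(),
        "n_mask_voxels": int(p.mask.sum()),
    }
    side_file = out_dir / "probmaps.json"
    side_file.write_text(json.dumps(sidecar, indent=2))
    return written + [mask_file, side_file]


def read_probmaps(in_dir) -> ProbMaps:
    """Read a ProbMaps directory written by :func:`write_probmaps`."""
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "probmaps.json").read_text())
    codes = np.array(sorted(sidecar["classes"].values()))
    names = {m.value: m.name for m in TissueLabel}
    maps = []
    affine = np.array(sidecar["affine"])
    for code in codes:
        vol = read_volume(in_dir / f"prob_{names[int(code)]}.nii.gz")
        maps.append(vol.data)
    mask = read_volume(in_dir / "mask.nii.gz").data.astype(bool)
    return ProbMaps(probs=np.stack(maps), mask=mask, affine=affine, class_codes=codes)


# ---------------------------------------------------------------------------
# Label / probability conversions

def majority_label(p: ProbMaps) -> LabelMap:
    """Hard segmentation: each masked voxel takes the class with the highest
    posterior probability; unmasked voxels are background.

    Ties are broken toward the lowest class code (np.argmax picks the first
    maximum, and class_codes are stored in ascending order), which makes the
    result deterministic and independent of evaluation order.
    """
    order = np.argsort(p.class_codes, kind="stable")
    probs_sorted = p.probs[order]
    codes_sorted = np.asarray(p.class_codes)[order]
    winner = codes_sorted[np.argmax(probs_sorted, axis=0)].astype(np.int16)
    winner[~p.mask] = TissueLabel.BG
    return LabelMap(data=winner, affine=p.affine.copy())


def one_hot_probmaps(lab: LabelMap, mask: np.ndarray | None = None) -> ProbMaps:
    """Encode a LabelMap as one-hot probability maps (probability 1 for the
    labelled class at each masked voxel)."""
    if mask is None:
        mask = lab.data != TissueLabel.BG
    codes = TissueLabel.codes()
    probs = np.zeros((len(codes),) + lab.data.shape, dtype=np.float32)
    for i, code in enumerate(codes):
        probs[i] = (lab.data == code) & mask
    return ProbMaps(probs=probs, mask=np.asarray(mask, dtype=bool), affine=lab.affine.copy(), class_codes=codes)
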