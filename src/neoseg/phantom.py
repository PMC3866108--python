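"""Synthetic multi-subject neonatal-brain-like phantoms with ground truth.

Each phantom subject is built from an analytic geometric model evaluated in
a canonical (atlas-like) coordinate system: an ellipsoidal brain with an
outer extracerebral-CSF shell, a cortical-grey-matter ribbon, an
unmyelinated-white-matter core, paired central-grey nuclei and ventricles,
sparse myelinated-white-matter tracts, a brainstem stalk and a cerebellar
lobe.  The eight tissue classes are disjoint by construction (later
structures overwrite earlier ones where they abut) and myelinated white
matter is deliberately rare (<2% of brain voxels), mirroring its rarity in
the neonatal brain at term-equivalent age.

Per subject, the canonical model is viewed through a random rigid
perturbation (the truth transform maps subject world coordinates to
canonical coordinates), class-conditional Gaussian intensities are drawn on
two channels with T1/T2-like contrast (CSF bright on T2, myelinated white
matter distinct on T1), optionally blurred, corrupted with additive noise,
and finally modulated by a smooth random multiplicative bias field per
channel.  All truths — labels, mask, transform, bias fields, unbiased
intensities — are returned, so registration, shading-correction and
segmentation accuracy can be scored against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from neoseg.imaging import LabelMap, TissueLabel, VolumeImage, write_labelmap, write_volume
from neoseg.preprocess import BiasField, _poly_terms
from neoseg.register import AffineTransform

# (T1 mean, T2 mean) per class: T2-weighted neonatal contrast — CSF/VENT
# bright on T2, unmyelinated WM brighter than grey matter on T2, myelinated
# WM distinct mainly on T1.
DEFAULT_MEANS: dict[str, tuple[float, float]] = {
    "BG": (15.0, 15.0),
    "CoGM": (135.0, 150.0),
    "CeGM": (142.0, 157.0),
    "UWM": (105.0, 190.0),
    "MWM": (185.0, 115.0),
    "CSF": (55.0, 250.0),
    "VENT": (60.0, 245.0),
    "BS": (150.0, 135.0),
    "CB": (128.0, 162.0),
}

# (name, center mm in canonical space, semi-axes mm); painted in order, so a
# later structure overwrites earlier tissue where they abut.
DEFAULT_STRUCTURES: list[tuple[str, tuple[float, float, float], tuple[float, float, float]]] = [
    ("CB", (0.0, -16.0, -22.0), (17.0, 14.0, 11.0)),
    ("BS", (0.0, 10.0, -26.0), (9.0, 9.0, 13.0)),
    ("CeGM", (16.0, -2.0, 0.0), (7.0, 8.0, 6.0)),
    ("CeGM", (-16.0, -2.0, 0.0), (7.0, 8.0, 6.0)),
    ("VENT", (8.0, 6.0, 6.0), (4.0, 10.0, 5.0)),
    ("VENT", (-8.0, 6.0, 6.0), (4.0, 10.0, 5.0)),
    ("MWM", (11.0, 0.0, 10.0), (3.0, 9.0, 5.0)),
    ("MWM", (-11.0, 0.0, 10.0), (3.0, 9.0, 5.0)),
]


@dataclass
class PhantomSpec:
    """Parameters of the phantom cohort.

    The default 96x96x48 grid at (1, 1, 2) mm is the fast profile used by
    the test suite; a 192x192x96 at (0.5, 0.5, 1) mm "full" profile exists
    for benchmarks.  Noise SD 6 on tissue means of 100-250 corresponds to
    an SNR of roughly 20-40, comfortably above clinical neonatal scans.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    brain_radii: tuple[float, float, float] = (38.0, 42.0, 36.0)
    csf_shell: float = 0.90     # CSF occupies radius fraction (csf_shell, 1]
    cogm_shell: float = 0.78    # CoGM ribbon (cogm_shell, csf_shell]
    inner_clip: float = 0.95    # deep structures stay inside this fraction
    class_means: dict[str, tuple[float, float]] = dc_field(default_factory=lambda: dict(DEFAULT_MEANS))
    class_sd: float = 4.0
    noise_sd: float = 6.0
    blur_sigma: float = 0.0     # voxels; boundary partial-volume stand-in
    bias_order: int = 2
    bias_amplitude: float = 0.08  # max |log field|
    shift_mm: float = 2.0
    rot_deg: float = 3.0
    structures: list = dc_field(default_factory=lambda: list(DEFAULT_STRUCTURES))
    seed: int = 42

    def validate(self) -> None:
        if not (0 < self.cogm_shell < self.csf_shell <= 1):
            raise ValueError("shell fractions must satisfy 0 < cogm < csf <= 1")
        if self.class_sd < 0 or self.noise_sd < 0:
            raise ValueError("intensity SDs must be >= 0")
        rx, ry, rz = self.brain_radii
        for name, c, r in self.structures:
            if name not in self.class_means:
                raise ValueError(f"structure {name} has no intensity entry")
            u = np.array(c) / np.array([rx, ry, rz])
            if np.linalg.norm(u) >= 1.0:
                raise ValueError(f"structure {name} centred outside the brain")

    def geometry(self) -> VolumeImage:
        """Canonical grid: axis-aligned, centred on the world origin."""
        shape = np.array(self.shape)
        spacing = np.array(self.spacing, dtype=float)
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = -(shape - 1) / 2.0 * spacing
        return VolumeImage(data=np.zeros(self.shape, dtype=np.float32), affine=affine)


def analytic_labels(spec: PhantomSpec, world_xyz: np.ndarray) -> np.ndarray:
    """Evaluate the analytic tissue model at (n, 3) canonical world points."""
    xyz = np.asarray(world_xyz, dtype=float)
    radii = np.array(spec.brain_radii)
    u = xyz / radii
    r = np.linalg.norm(u, axis=1)
    codes = np.zeros(len(xyz), dtype=np.int16)
    codes[r <= 1.0] = TissueLabel.CSF
    codes[r <= spec.csf_shell] = TissueLabel.CoGM
    codes[r <= spec.cogm_shell] = TissueLabel.UWM
    inner = r <= spec.inner_clip
    for name, center, sradii in spec.structures:
        d = (xyz - np.array(center)) / np.array(sradii)
        inside = (np.einsum("ij,ij->i", d, d) <= 1.0) & inner
        codes[inside] = TissueLabel[name]
    return codes


@dataclass
class PhantomTruth:
    """Everything the generator knows and downstream recovery tests score."""

    to_canonical: AffineTransform      # subject world -> canonical (atlas) world
    bias_t1: BiasField
    bias_t2: BiasField
    t1_unbiased: VolumeImage           # noisy but bias-free intensities
    t2_unbiased: VolumeImage
    subject_seed: int


@dataclass
class PhantomSubject:
    t1: VolumeImage
    t2: VolumeImage
    labels: LabelMap
    mask: np.ndarray
    truth: PhantomTruth


def _random_rigid(rng: np.random.Generator, shift_mm: float, rot_deg: float) -> AffineTransform:
    t = rng.uniform(-shift_mm, shift_mm, size=3)
    angles = np.deg2rad(rng.uniform(-rot_deg, rot_deg, size=3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = np.eye(4)
    m[:3, :3] = rot_z @ rot_y @ rot_x
    m[:3, 3] = t
    return AffineTransform(m)


def _random_bias(
    spec: PhantomSpec, rng: np.random.Generator, bbox_low: np.ndarray, bbox_high: np.ndarray
) -> BiasField:
    terms = _poly_terms(spec.bias_order)
    coeffs = rng.uniform(-1.0, 1.0, size=len(terms))
    f = BiasField(
        coefficients=coeffs, terms=terms, order=spec.bias_order,
        bbox_low=bbox_low, bbox_high=bbox_high,
    )
    if spec.bias_amplitude == 0:
        f.coefficients[:] = 0.0
        return f
    # scale so the log field peaks at the requested amplitude over the brain
    # (sample points inside the inscribed ellipsoid of the bounding box)
    grid = np.stack(np.meshgrid(*[np.linspace(lo, hi, 11) for lo, hi in zip(bbox_low, bbox_high)],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    center = (bbox_low + bbox_high) / 2.0
    half = np.maximum((bbox_high - bbox_low) / 2.0, 1e-9)
    inside = (((grid - center) / half) ** 2).sum(axis=1) <= 1.0
    lf = f.log_field(grid[inside])
    lf = lf - lf.mean()
    peak = np.abs(lf).max()
    f.coefficients *= spec.bias_amplitude / max(peak, 1e-12)
    return f


def make_subject(spec: PhantomSpec, subject_seed: int) -> PhantomSubject:
    """Generate one phantom subject. Bit-reproducible for a given seed."""
    spec.validate()
    rng = np.random.default_rng(subject_seed)
    geo = spec.geometry()

    to_canonical = _random_rigid(rng, spec.shift_mm, spec.rot_deg)

    idx = np.indices(spec.shape).reshape(3, -1).T
    world = geo.world_coordinates(idx)
    codes = analytic_labels(spec, to_canonical.apply(world)).reshape(spec.shape)
    labels = LabelMap(data=codes, affine=geo.affine.copy())
    mask = codes != TissueLabel.BG

    means_t1 = np.zeros(len(TissueLabel))
    means_t2 = np.zeros(len(TissueLabel))
    for m in TissueLabel:
        mt1, mt2 = spec.class_means[m.name]
        means_t1[m.value], means_t2[m.value] = mt1, mt2

    clean_t1 = means_t1[codes]
    clean_t2 = means_t2[codes]
    if spec.blur_sigma > 0:
        sig = (spec.blur_sigma,) * 3
        clean_t1 = ndimage.gaussian_filter(clean_t1, sig)
        clean_t2 = ndimage.gaussian_filter(clean_t2, sig)

    total_sd = float(np.hypot(spec.class_sd, spec.noise_sd))
    t1_unb = clean_t1 + rng.normal(0.0, total_sd, size=spec.shape)
    t2_unb = clean_t2 + rng.normal(0.0, total_sd, size=spec.shape)

    if mask.any():
        mask_world = geo.world_coordinates(np.argwhere(mask))
        lo, hi = mask_world.min(axis=0), mask_world.max(axis=0)
    else:
        lo, hi = world.min(axis=0), world.max(axis=0)
    bias_t1 = _random_bias(spec, rng, lo, hi)
    bias_t2 = _random_bias(spec, rng, lo, hi)

    f1 = np.exp(bias_t1.log_field(world)).reshape(spec.shape)
    f2 = np.exp(bias_t2.log_field(world)).reshape(spec.shape)

    t1 = VolumeImage(data=(t1_unb * f1).astype(np.float32), affine=geo.affine.copy())
    t2 = VolumeImage(data=(t2_unb * f2).astype(np.float32), affine=geo.affine.copy())
    truth = PhantomTruth(
        to_canonical=to_canonical,
        bias_t1=bias_t1,
        bias_t2=bias_t2,
        t1_unbiased=VolumeImage(data=t1_unb.astype(np.float32), affine=geo.affine.copy()),
        t2_unbiased=VolumeImage(data=t2_unb.astype(np.float32), affine=geo.affine.copy()),
        subject_seed=subject_seed,
    )
    return PhantomSubject(t1=t1, t2=t2, labels=labels, mask=mask, truth=truth)


def make_cohort(spec: PhantomSpec, n: int, out_dir=None) -> list[PhantomSubject]:
    """Generate n subjects with independent seeds derived from spec.seed.

    With ``out_dir`` set, each subject is written to
    ``subject-XX/{t1,t2,labels,mask}.nii.gz`` plus a ``truth.json`` and a
    cohort ``manifest.json``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    seed_rng = np.random.default_rng(spec.seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=n)
    subjects = [make_subject(spec, int(s)) for s in seeds]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"n": n, "seed": spec.seed, "subject_seeds": [int(s) for s in seeds],
                    "shape": list(spec.shape), "spacing": list(spec.spacing)}
        for i, sub in enumerate(subjects):
            sdir = out_dir / f"subject-{i:02d}"
            sdir.mkdir(exist_ok=True)
            write_volume(sub.t1, sdir / "t1.nii.gz")
            write_volume(sub.t2, sdir / "t2.nii.gz")
            write_labelmap(sub.labels, sdir / "labels.nii.gz")
            write_volume(VolumeImage(sub.mask.astype(np.float32), sub.t1.affine), sdir / "mask.nii.gz")
            truth = {
                "subject_seed": sub.truth.subject_seed,
                "to_canonical": sub.truth.to_canonical.to_json_dict(),
                "bias_t1_coefficients": sub.truth.bias_t1.coefficients.tolist(),
                "bias_t2_coefficients": sub.truth.bias_t2.coefficients.tolist(),
                "bias_order": sub.truth.bias_t1.order,
            }
            (sdir / "truth.json").write_text(json.dumps(truth, indent=2))
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return subjects


def analytic_volumes(spec: PhantomSpec, oversample: int = 2) -> dict[str, float]:
    """Per-class volumes in cc from the analytic model, evaluated on an
    ``oversample``-times finer canonical grid (independent of any generated
    subject's voxelization)."""
    shape = tuple(int(s * oversample) for s in spec.shape)
    spacing = tuple(s / oversample for s in spec.spacing)
    fine = replace(spec, shape=shape, spacing=spacing)
    geo = fine.geometry()
    idx = np.indices(shape).reshape(3, -1).T
    codes = analytic_labels(spec, geo.world_coordinates(idx))
    vox_cc = np.prod(spacing) / 1000.0
    return {m.name: float((codes == m.value).sum() * vox_cc) for m in TissueLabel if m != TissueLabel.BG}
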