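"""Affine mutual-information registration, iterative average-atlas
construction, and transform application/inversion.

Transforms are 4x4 homogeneous matrices mapping *fixed-image world
coordinates to moving-image world coordinates* (RAS+, mm) — the resampling
convention: to fill a voxel of the fixed grid, push its world position
through the transform and interpolate the moving image there.

The built-in backend optimizes negative mutual information over three
resolutions (subsampling factor 2 per level) with randomly sampled voxels
and a gradient-descent optimizer, via SimpleITK.  An elastic (B-spline)
stage can be supplied as an external backend with the same call signature;
the built-in backend is affine-only, which suffices for phantom-scale
validation where the inter-subject deformations are rigid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from neoseg.imaging import VolumeImage

_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class AffineTransform:
    """Invertible linear + translation map between two world spaces (mm)."""

    matrix: np.ndarray  # 4x4, fixed-world -> moving-world

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = t
        return cls(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) world points through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return AffineTransform(self.matrix @ other.matrix)

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def to_json_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "convention": "fixed_world_to_moving_world_RAS_mm"}


def invert(t: AffineTransform) -> AffineTransform:
    """Matrix inverse; forward∘inverse is identity to 1e-6."""
    return AffineTransform(np.linalg.inv(t.matrix))


@dataclass
class RegistrationOptions:
    """Tunables for the mutual-information affine registration.

    Defaults: 3 resolutions with subsampling factor 2 per level, 200
    optimizer iterations per level, 5000 random metric samples per
    iteration, 32 histogram bins.
    """

    resolutions: int = 3
    iterations: int = 200
    samples: int = 5000
    histogram_bins: int = 32
    seed: int = 12345
    rigid_only: bool = False


def _to_sitk(vol: VolumeImage) -> sitk.Image:
    """Convert to a SimpleITK image (which uses LPS world coordinates)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T, dtype=np.float32))
    aff = _RAS2LPS @ vol.affine
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    direction = aff[:3, :3] / spacing
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in aff[:3, 3]))
    img.SetDirection(tuple(direction.flatten()))
    return img


def _sitk_transform_to_matrix(tf: sitk.Transform) -> np.ndarray:
    """Flatten a (possibly composite) sitk transform into a 4x4 LPS matrix."""
    tf = sitk.CompositeTransform(tf) if not isinstance(tf, sitk.CompositeTransform) else tf
    m = np.eye(4)
    # Composite applies the *last added* transform first; the overall map is
    # T_0 ∘ T_1 ∘ ... so multiply left-to-right.
    for i in range(tf.GetNumberOfTransforms()):
        sub = tf.GetNthTransform(i)
        a = np.array(sub.GetMatrix()).reshape(3, 3)
        c = np.array(sub.GetCenter())
        t = np.array(sub.GetTranslation())
        sm = np.eye(4)
        sm[:3, :3] = a
        sm[:3, 3] = t + c - a @ c
        m = m @ sm
    return m


def register_affine(
    fixed: VolumeImage,
    moving: VolumeImage,
    opts: RegistrationOptions | None = None,
) -> AffineTransform:
    """Affine registration of ``moving`` onto ``fixed`` by maximizing mutual
    information (equivalently, minimizing the negative-MI cost).

    Returns the transform mapping fixed world coordinates to moving world
    coordinates.  Deterministic for a fixed ``opts.seed``.
    """
    opts = opts or RegistrationOptions()
    for name, vol in (("fixed", fixed), ("moving", moving)):
        if np.ptp(vol.data) == 0:
            raise ValueError(f"register_affine: {name} image is constant")

    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)  # reproducible sums
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)

    def _method(initial: sitk.Transform) -> sitk.ImageRegistrationMethod:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=opts.histogram_bins)
        n_vox = int(np.prod(fixed.shape))
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(min(1.0, opts.samples / max(n_vox, 1)), opts.seed)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=2.0,
            minStep=1e-5,
            numberOfIterations=opts.iterations,
            relaxationFactor=0.7,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        shrink = [2 ** (opts.resolutions - 1 - i) for i in range(opts.resolutions)]
        reg.SetShrinkFactorsPerLevel(shrink)
        reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(initial, inPlace=False)
        return reg

    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    try:
        # rigid stage for a robust coarse alignment
        rigid = sitk.CompositeTransform(_method(init).Execute(f_img, m_img))
        final: sitk.Transform = rigid
        if not opts.rigid_only:
            e = sitk.Euler3DTransform(rigid.GetNthTransform(0))
            aff = sitk.AffineTransform(3)
            aff.SetMatrix(e.GetMatrix())
            aff.SetCenter(e.GetCenter())
            aff.SetTranslation(e.GetTranslation())
            final = _method(aff).Execute(f_img, m_img)
    except RuntimeError as exc:
        warnings.warn(f"registration optimizer failed ({exc}); returning initial transform")
        final = init

    m_lps = _sitk_transform_to_matrix(final)
    m_ras = _RAS2LPS @ m_lps @ _RAS2LPS
    return AffineTransform(m_ras)


def resample(
    moving: VolumeImage,
    t: AffineTransform,
    target: VolumeImage,
    interp: str = "linear",
) -> VolumeImage:
    """Sample ``moving`` on the ``target`` grid through ``t``.

    For each target voxel, its world position is mapped by ``t`` into the
    moving image's world space and interpolated there (``linear`` for
    intensities and probabilities, ``nearest`` for labels).  Voxels mapping
    outside the moving field of view are 0.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    # target index -> target world -> moving world -> moving index
    full = np.linalg.inv(moving.affine) @ t.matrix @ target.affine
    order = 1 if interp == "linear" else 0
    out = ndimage.affine_transform(
        np.asarray(moving.data, dtype=np.float32),
        full[:3, :3],
        offset=full[:3, 3],
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    return VolumeImage(data=out, affine=target.affine.copy())


@dataclass
class AtlasResult:
    """Average brain built by iterative registration and averaging."""

    atlas: VolumeImage
    transforms: list[AffineTransform]
    iterations_run: int
    convergence_trace: list[float] = field(default_factory=list)


def build_atlas(
    t2s: list[VolumeImage],
    max_iter: int = 5,
    tol: float | None = None,
    opts: RegistrationOptions | None = None,
) -> AtlasResult:
    """Construct an average brain image from the cohort's T2 volumes.

    Starts from the plain voxelwise mean (so no single subject serves as
    the reference), then repeatedly registers every subject to the current
    average, resamples, and re-averages, until the mean absolute change of
    the average drops below ``tol`` (default 0.5% of the initial intensity
    range) or ``max_iter`` is reached.
    """
    if len(t2s) < 2:
        raise ValueError("build_atlas requires at least 2 subjects")
    ref = t2s[0]
    aligned = []
    for v in t2s:
        if v.same_geometry(ref):
            aligned.append(np.asarray(v.data, dtype=np.float64))
        else:
            aligned.append(np.asarray(resample(v, AffineTransform.identity(), ref).data, dtype=np.float64))
    avg = np.mean(aligned, axis=0)
    atlas = VolumeImage(data=avg.astype(np.float32), affine=ref.affine.copy())
    if tol is None:
        tol = 0.005 * float(np.ptp(avg))

    transforms = [AffineTransform.identity() for _ in t2s]
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        resampled = []
        new_transforms = []
        for v in t2s:
            t = register_affine(atlas, v, opts)
            new_transforms.append(t)
            resampled.append(np.asarray(resample(v, t, atlas).data, dtype=np.float64))
        new_avg = np.mean(resampled, axis=0)
        change = float(np.mean(np.abs(new_avg - avg)))
        trace.append(change)
        avg = new_avg
        atlas = VolumeImage(data=avg.astype(np.float32), affine=ref.affine.copy())
        transforms = new_transforms
        if change < tol:
            break
    else:
        it = max_iter

    if max_iter == 0:
        it = 0
    return AtlasResult(atlas=atlas, transforms=transforms, iterations_run=it, convergence_trace=trace)


def to_atlas_coords(
    subject_t2: VolumeImage,
    atlas: VolumeImage,
    opts: RegistrationOptions | None = None,
) -> AffineTransform:
    """Register a subject's T2 volume to the average brain.

    Returns the transform mapping atlas world coordinates to subject world
    coordinates (the resampling direction).  Its inverse maps subject
    voxels into atlas space, which is what the spatial features use.
    """
    return register_affine(atlas, subject_t2, opts)
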