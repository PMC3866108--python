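"""Overlap metrics, tissue volumetry, volume-comparison statistics, and the
leave-one-out evaluation harness.

Binary segmentations are compared per class with the Dice similarity
coefficient DSC = 2TP/(2TP + FP + FN), sensitivity TP/(TP+FN) and
specificity TN/(TN+FP), all counted over a configurable voxel universe.
Tissue volumes are computed two ways: directly from the probability maps
(sum of posteriors times voxel volume) and from the binary majority-class
segmentation (voxel count times voxel volume).  Automatic volumes are
compared with reference volumes by a paired-samples t-test with Bonferroni
correction at a 0.01 significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from neoseg.imaging import LabelMap, ProbMaps, TissueLabel, majority_label
from neoseg.preprocess import correct_shading
from neoseg.register import RegistrationOptions, build_atlas, invert
from neoseg.features import background_shell, extract_features, subsample_training
from neoseg.classify import (
    DEFAULT_K,
    native_neighbor_counts,
    probmaps_from_counts,
    train_model,
)

SIGNIFICANCE_ALPHA = 0.01


@dataclass
class OverlapResult:
    """Per-class confusion counts and the derived overlap metrics."""

    tissue: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def dsc(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        if denom == 0:
            return 1.0  # both sets empty within the universe
        return 2.0 * self.tp / denom

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")


def _universe_mask(universe, pred: LabelMap, ref: LabelMap) -> np.ndarray:
    if isinstance(universe, np.ndarray):
        u = np.asarray(universe, dtype=bool)
    elif universe == "image":
        u = np.ones(pred.shape, dtype=bool)
    elif universe == "bounding_box":
        fg = (pred.data != 0) | (ref.data != 0)
        if not fg.any():
            return fg
        u = np.zeros(pred.shape, dtype=bool)
        sl = tuple(slice(a.min(), a.max() + 1) for a in np.nonzero(fg))
        u[sl] = True
    else:
        raise ValueError(f"unknown universe {universe!r}")
    # always include the reference foreground so FN voxels are countable
    return u | (ref.data != 0)


def overlap(
    pred: LabelMap,
    ref: LabelMap,
    tissue: TissueLabel,
    universe,
) -> OverlapResult:
    """Confusion counts and DSC/sensitivity/specificity for one class.

    ``universe`` is a boolean voxel set (typically the brain mask; the
    reference foreground is always included), or "image"/"bounding_box".
    """
    if not pred.same_geometry(ref):
        raise ValueError("pred/ref geometry mismatch")
    u = _universe_mask(universe, pred, ref)
    if not u.any():
        raise ValueError("empty metric universe")
    p = pred.data[u] == int(tissue)
    r = ref.data[u] == int(tissue)
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    tn = int(np.sum(~p & ~r))
    return OverlapResult(tissue=TissueLabel(tissue).name, tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class VolumeReport:
    """Per-class tissue volumes in cc, probabilistic and binary."""

    voxel_volume_mm3: float
    probabilistic_cc: dict[str, float]
    binary_cc: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"tissue": t, "vol_prob_cc": self.probabilistic_cc[t], "vol_binary_cc": self.binary_cc[t]}
            for t in self.probabilistic_cc
        ]
        return pd.DataFrame(rows)


def volumes(p: ProbMaps, b: LabelMap | None = None) -> VolumeReport:
    """Tissue volumes from the probability maps (sum of posteriors x voxel
    volume) and from the binary majority-class segmentation."""
    if b is None:
        b = majority_label(p)
    if not p.same_geometry(b):
        raise ValueError("ProbMaps/LabelMap geometry mismatch")
    vv = p.voxel_volume_mm3
    prob_cc: dict[str, float] = {}
    bin_cc: dict[str, float] = {}
    for ci, code in enumerate(p.class_codes):
        name = TissueLabel(int(code)).name
        prob_cc[name] = float(p.probs[ci].sum(dtype=np.float64)) * vv / 1000.0
        # binary counts restricted to the mask, so BG outside the brain does
        # not inflate the background volume
        bin_cc[name] = float(((b.data == int(code)) & p.mask).sum()) * vv / 1000.0
    return VolumeReport(voxel_volume_mm3=vv, probabilistic_cc=prob_cc, binary_cc=bin_cc)


def compare_volumes(auto: pd.DataFrame, ref: pd.DataFrame, alpha: float = SIGNIFICANCE_ALPHA) -> pd.DataFrame:
    """Paired-samples t-test per tissue class with Bonferroni correction.

    ``auto`` and ``ref`` are (subject x tissue) volume tables: one row per
    subject, one column per tissue class, in matching subject order.
    """
    if list(auto.index) != list(ref.index) or set(auto.columns) != set(ref.columns):
        raise ValueError("auto/ref volume tables must cover identical subjects and classes")
    if len(auto) < 3:
        raise ValueError("paired t-test requires at least 3 subjects")
    n_classes = len(auto.columns)
    rows = []
    for tissue in auto.columns:
        a, r = auto[tissue].to_numpy(float), ref[tissue].to_numpy(float)
        if np.allclose(a, r):
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat, p_raw = stats.ttest_rel(a, r)
            if np.isnan(p_raw):
                p_raw = 1.0
        p_adj = min(1.0, float(p_raw) * n_classes)
        rows.append(
            {"tissue": tissue, "t": float(t_stat), "p_raw": float(p_raw),
             "p_bonferroni": p_adj, "significant": p_adj < alpha}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Leave-one-out harness

@dataclass
class LooOptions:
    """Tunables of the leave-one-out evaluation.

    Defaults follow the segmentation method's operating point: k=50
    neighbours, 20% of brain voxels sampled per training image, no
    imbalance weighting.  ``compare_exponent`` additionally evaluates the
    weighted posteriors from the same neighbour search and reports the
    fraction of masked voxels whose majority label agrees with the
    unweighted result.
    """

    k: int = DEFAULT_K
    fraction: float = 0.20
    seed: int = 0
    exponent: float | None = None
    compare_exponent: float | None = None
    shading: bool = True
    shading_order: int = 2
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    atlas_max_iter: int = 2
    train_background_shell: bool = True
    universe: str | np.ndarray = "mask"


@dataclass
class LooSubjectResult:
    subject: int
    overlaps: list[OverlapResult]
    volume_report: VolumeReport
    reference_cc: dict[str, float]
    weighting_agreement: float | None = None
    probmaps: ProbMaps | None = None
    pred_labels: LabelMap | None = None


@dataclass
class LooResult:
    subjects: list[LooSubjectResult]
    atlas_iterations: int

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for sr in self.subjects:
            for ov in sr.overlaps:
                rows.append(
                    {
                        "subject": sr.subject,
                        "tissue": ov.tissue,
                        "DSC": ov.dsc,
                        "sensitivity": ov.sensitivity,
                        "specificity": ov.specificity,
                        "vol_prob_cc": sr.volume_report.probabilistic_cc[ov.tissue],
                        "vol_binary_cc": sr.volume_report.binary_cc[ov.tissue],
                        "vol_ref_cc": sr.reference_cc[ov.tissue],
                    }
                )
        return pd.DataFrame(rows)


def leave_one_out(subjects, opts: LooOptions | None = None, keep_probmaps: bool = False) -> LooResult:
    """Leave-one-out evaluation over a cohort.

    Each subject in turn is segmented by a classifier trained on the
    remaining subjects (per-image random subsampling of the training
    voxels), using an average-brain atlas built once from the full cohort
    for the spatial features.  Returns per-subject, per-class overlap
    metrics and volumes; deterministic for fixed seeds.

    ``subjects`` is a list of objects with attributes t1, t2, labels, mask
    (the phantom generator's subjects qualify).
    """
    opts = opts or LooOptions()
    if len(subjects) < 2:
        raise ValueError("leave_one_out requires at least 2 subjects")

    # 1) shading correction
    t1s, t2s = [], []
    for si, sub in enumerate(subjects):
        if opts.shading:
            t1c, _ = correct_shading(sub.t1, sub.mask, opts.shading_order, seed=opts.seed + 17 * si)
            t2c, _ = correct_shading(sub.t2, sub.mask, opts.shading_order, seed=opts.seed + 17 * si + 1)
        else:
            t1c, t2c = sub.t1, sub.t2
        t1s.append(t1c)
        t2s.append(t2c)

    # 2) atlas from all subjects' T2 volumes (built once, reused per fold)
    atlas_res = build_atlas(t2s, max_iter=opts.atlas_max_iter, opts=opts.registration)
    to_atlas = [invert(t) for t in atlas_res.transforms]  # subject world -> atlas world

    # 3) per-subject feature tables (training mask includes a thin
    # background shell so the BG class has samples)
    tables = []
    for si, sub in enumerate(subjects):
        train_mask = np.asarray(sub.mask, dtype=bool)
        if opts.train_background_shell:
            train_mask = train_mask | background_shell(train_mask)
        tables.append(extract_features(t1s[si], t2s[si], train_mask, to_atlas[si], labels=sub.labels))

    tissue_names = [m.name for m in TissueLabel.tissue_classes()]
    results = []
    for held in range(len(subjects)):
        train_tables = [t for si, t in enumerate(tables) if si != held]
        training = subsample_training(train_tables, fraction=opts.fraction, seed=opts.seed + 1000 + held)
        model = train_model(training, k=opts.k)

        sub = subjects[held]
        counts, ijk = native_neighbor_counts(model, t1s[held], t2s[held], sub.mask, to_atlas[held])
        probmaps = probmaps_from_counts(
            counts, ijk, sub.t1.shape, sub.t1.affine, sub.mask, model.class_codes,
            weighting=opts.exponent,
        )
        pred = majority_label(probmaps)

        agreement = None
        if opts.compare_exponent is not None:
            weighted = probmaps_from_counts(
                counts, ijk, sub.t1.shape, sub.t1.affine, sub.mask, model.class_codes,
                weighting=opts.compare_exponent,
            )
            pred_w = majority_label(weighted)
            m = np.asarray(sub.mask, dtype=bool)
            agreement = float(np.mean(pred.data[m] == pred_w.data[m]))

        universe = sub.mask if opts.universe == "mask" else opts.universe
        overlaps = [
            overlap(pred, sub.labels, TissueLabel[name], universe) for name in tissue_names
        ]
        vol = volumes(probmaps, pred)
        ref_cc = {
            name: float((sub.labels.data == int(TissueLabel[name])).sum())
            * sub.labels.voxel_volume_mm3 / 1000.0
            for name in tissue_names
        }
        results.append(
            LooSubjectResult(
                subject=held,
                overlaps=overlaps,
                volume_report=vol,
                reference_cc=ref_cc,
                weighting_agreement=agreement,
                probmaps=probmaps if keep_probmaps else None,
                pred_labels=pred if keep_probmaps else None,
            )
        )
    return LooResult(subjects=results, atlas_iterations=atlas_res.iterations_run)
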