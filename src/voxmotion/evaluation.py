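"""Tracking metrics, Jacobian diagnostics, ITV baseline and trace reports.

Geometric accuracy is scored with the Dice similarity coefficient
(DSC = 2|G∩P| / (|G|+|P|), averaged over timesteps for sequences) and the
target centroid error CE_t = ||mu_P(t) - mu_G(t)||_2 in mm; image accuracy
with a global single-window SSIM; and deformation plausibility with the
fraction of voxels where the Jacobian determinant of the predicted mapping
is non-positive.

The standard-of-care comparator is the internal target volume (ITV): the
union of the target over the breathing cycle, observed from a static beam
frame.  The tracked alternative shifts the beam by the predicted target
centroid motion; the volume traversed by the target in that moving frame
("dynamically shifted target volume") shrinks toward the single-phase
target volume as prediction quality improves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import shift as nd_shift

from .fields import (
    DisplacementField,
    Mask3D,
    Volume3D,
    jacobian_determinant,
    negative_jacobian_fraction,
    warp_mask,
    warp_volume,
)
from .imaging import NoiseModel, add_noise, extract_slices, forward_project, to_kspace
from .networks import Network, NetworkInputs, predict_dvf
from .phantom import IntrafractionSequence

__all__ = [
    "MetricsReport",
    "TrackingTrace",
    "dice",
    "dice_sequence",
    "centroid_error",
    "ssim",
    "build_itv",
    "build_dynamic_volume",
    "evaluate_sequence",
    "oracle_predictor",
    "identity_predictor",
]

AXES = ("LR", "AP", "SI")


def dice(G: Mask3D, P: Mask3D) -> float:
    """Dice similarity 2|G∩P| / (|G|+|P|); undefined (nan) if both empty."""
    if G.grid != P.grid:
        raise ValueError("dice requires masks on the same grid")
    g = G.values.astype(bool)
    p = P.values.astype(bool)
    denom = int(g.sum()) + int(p.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((g & p).sum()) / denom


def dice_sequence(G_seq, P_seq) -> float:
    """Timestep-averaged Dice over paired mask sequences."""
    vals = [dice(g, p) for g, p in zip(G_seq, P_seq)]
    return float(np.nanmean(vals))


def centroid_error(G: Mask3D, P: Mask3D) -> float:
    """Euclidean distance (mm) between unweighted mask centroids."""
    if G.grid != P.grid:
        raise ValueError("centroid_error requires masks on the same grid")
    return float(np.linalg.norm(P.centroid_mm() - G.centroid_mm()))


def ssim(x: Volume3D, y: Volume3D, mask: Mask3D | None = None) -> float:
    """Global single-window structural similarity of y against ground truth x.

    Uses the conventional stabilisers c1 = (0.01 L)^2, c2 = (0.03 L)^2 with
    L the dynamic range of the ground-truth volume; restricted to ``mask``
    when given.  Identical volumes score 1 even at zero dynamic range.
    """
    if x.grid != y.grid:
        raise ValueError("ssim requires volumes on the same grid")
    if mask is not None:
        sel = mask.values.astype(bool)
        a, b = x.values[sel], y.values[sel]
    else:
        a, b = x.values.ravel(), y.values.ravel()
    L = float(a.max() - a.min())
    if L == 0:
        return 1.0 if np.array_equal(a, b) else float("nan")
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    mu_x, mu_y = a.mean(), b.mean()
    var_x, var_y = a.var(), b.var()
    cov = ((a - mu_x) * (b - mu_y)).mean()
    return float(
        (2 * mu_x * mu_y + c1) * (2 * cov + c2) / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


def build_itv(target_masks) -> Mask3D:
    """Internal target volume: voxelwise union of the target over time."""
    masks = list(target_masks)
    if not masks:
        raise ValueError("ITV requires at least one mask")
    union = np.zeros_like(masks[0].values)
    for m in masks:
        union |= m.values
    return Mask3D(masks[0].grid, union)


def build_dynamic_volume(target_masks, predicted_shifts_mm) -> Mask3D:
    """Volume traversed by the target in the dynamically shifted beam frame.

    Each timestep's target mask is translated by the negative of the
    predicted centroid displacement (nearest-voxel shift) before the union;
    perfect prediction of rigid motion collapses the union to the
    single-phase target.
    """
    masks = list(target_masks)
    shifts = np.asarray(predicted_shifts_mm, dtype=float)
    if len(masks) != len(shifts):
        raise ValueError("one predicted shift per timestep is required")
    union = np.zeros_like(masks[0].values)
    spacing = np.asarray(masks[0].grid.spacing)
    for m, s in zip(masks, shifts):
        vox = np.round(-s / spacing).astype(int)
        moved = nd_shift(m.values, vox, order=0, mode="constant", cval=0)
        union |= moved.astype(np.uint8)
    return Mask3D(masks[0].grid, union)


@dataclass
class TrackingTrace:
    """Ground-truth vs predicted target centroid displacement per axis (mm)."""

    time_s: np.ndarray
    truth_mm: np.ndarray  # (N, 3) on (LR, AP, SI)
    predicted_mm: np.ndarray

    def to_csv(self, path: str) -> None:
        import pandas as pd

        rows = []
        for i, t in enumerate(self.time_s):
            for a, name in enumerate(AXES):
                rows.append(
                    {
                        "time": float(t),
                        "axis": name,
                        "truth_mm": float(self.truth_mm[i, a]),
                        "predicted_mm": float(self.predicted_mm[i, a]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class MetricsReport:
    """Per-timestep metrics with summary statistics and volume comparison."""

    dsc: dict[str, np.ndarray]  # per structure
    centroid_error_mm: np.ndarray  # target
    ssim: np.ndarray
    neg_jacobian_fraction: np.ndarray
    itv_volume_mm3: float
    dynamic_volume_mm3: float
    #: standard-of-care comparator: distance of the true target centroid from
    #: the (static) ITV centroid at each timestep
    itv_baseline_ce_mm: np.ndarray | None = None

    @property
    def percent_volume_reduction(self) -> float:
        if self.itv_volume_mm3 <= 0:
            return float("nan")
        return 100.0 * (1.0 - self.dynamic_volume_mm3 / self.itv_volume_mm3)

    def summary(self) -> dict:
        out = {
            "ce_mean_mm": float(np.mean(self.centroid_error_mm)),
            "ce_std_mm": float(np.std(self.centroid_error_mm)),
            "ssim_mean": float(np.nanmean(self.ssim)),
            "ssim_std": float(np.nanstd(self.ssim)),
            "neg_jacobian_fraction_max": float(np.max(self.neg_jacobian_fraction)),
            "itv_volume_mm3": self.itv_volume_mm3,
            "dynamic_volume_mm3": self.dynamic_volume_mm3,
            "percent_volume_reduction": self.percent_volume_reduction,
        }
        if self.itv_baseline_ce_mm is not None:
            out["itv_ce_mean_mm"] = float(np.mean(self.itv_baseline_ce_mm))
            out["itv_ce_std_mm"] = float(np.std(self.itv_baseline_ce_mm))
        oar_means = []
        for name, vals in self.dsc.items():
            out[f"dsc_{name}_mean"] = float(np.nanmean(vals))
            if name != "target":
                oar_means.append(np.nanmean(vals))
        if oar_means:
            out["dsc_oar_mean"] = float(np.mean(oar_means))
        return out

    def to_csv(self, path: str) -> None:
        import pandas as pd

        data = {"timestep": np.arange(len(self.centroid_error_mm))}
        for name, vals in self.dsc.items():
            data[f"dsc_{name}"] = vals
        data["ce_mm"] = self.centroid_error_mm
        data["ssim"] = self.ssim
        data["neg_jacobian_fraction"] = self.neg_jacobian_fraction
        pd.DataFrame(data).to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.summary(), f, indent=2)


def oracle_predictor(i: int, sequence: IntrafractionSequence) -> DisplacementField:
    """Upper-bound "network": returns the ground-truth DVF."""
    return sequence.dvf_at(i)


def identity_predictor(i: int, sequence: IntrafractionSequence) -> DisplacementField:
    """Static baseline "network": predicts no motion."""
    return DisplacementField.identity(sequence.phantom.grid, provenance="predicted")


def _network_inputs(net: Network, sequence: IntrafractionSequence, i: int, noise: NoiseModel | None):
    """Synthesize this timestep's 2D inputs for the network's modality."""
    ph = sequence.phantom
    arch = net.spec.architecture
    acquired = sequence.volume_at(i)
    if arch in ("A", "B", "C"):
        angle = float(sequence.angles_deg[i])
        ref_p = forward_project(ph.reference, angle)
        acq_p = forward_project(acquired, angle)
        if noise is not None:
            acq_p = add_noise(acq_p, NoiseModel(
                count_scale=noise.count_scale,
                scatter_fraction=noise.scatter_fraction,
                scatter_blur_mm=noise.scatter_blur_mm,
                attenuation=noise.attenuation,
                seed=noise.seed + i,
            ))
        x, y = ref_p.pixels.astype(np.float32), acq_p.pixels.astype(np.float32)
        if arch == "A":
            return NetworkInputs("A", [np.stack([x, y])])
        if arch == "B":
            return NetworkInputs("B", [x[None], y[None]])
        return NetworkInputs("C", [y[None]], volume=ph.reference.values.astype(np.float32))
    c = ph.grid.shape[1] // 2
    s = ph.grid.shape[0] // 2
    ref = extract_slices(ph.reference, c, s)
    acq = extract_slices(acquired, c, s)
    if arch == "D":
        return NetworkInputs(
            "D",
            [
                np.stack([ref.coronal, ref.sagittal]).astype(np.float32),
                np.stack([acq.coronal, acq.sagittal]).astype(np.float32),
            ],
        )
    xc, xs = to_kspace(ref.coronal), to_kspace(ref.sagittal)
    yc, ys = to_kspace(acq.coronal), to_kspace(acq.sagittal)
    return NetworkInputs(
        "E",
        [
            np.stack([xc[0], yc[0]]).astype(np.float32),
            np.stack([xs[0], ys[0]]).astype(np.float32),
            np.stack([xc[1], yc[1]]).astype(np.float32),
            np.stack([xs[1], ys[1]]).astype(np.float32),
        ],
    )


def evaluate_sequence(
    predictor,
    sequence: IntrafractionSequence,
    noise: NoiseModel | None = None,
    structures: tuple[str, ...] | None = None,
) -> tuple[MetricsReport, TrackingTrace]:
    """Run a predictor along an intrafraction sequence and score it.

    ``predictor`` is either a trained :class:`Network` (2D inputs are
    synthesised per timestep, with optional acquired-image noise) or a
    callable ``(i, sequence) -> DisplacementField`` such as
    :func:`oracle_predictor`.  Per timestep the reference structures and
    volume are warped by the prediction and compared against the
    ground-truth instantaneous anatomy.
    """
    ph = sequence.phantom
    ref_masks = ph.reference_structures
    names = structures or tuple(ref_masks.keys())
    if isinstance(predictor, Network):
        if predictor.spec.output_grid.shape != ph.grid.shape:
            raise ValueError("network output grid does not match the phantom grid")

    n = len(sequence)
    dsc = {name: np.zeros(n) for name in names}
    ce = np.zeros(n)
    ssim_vals = np.zeros(n)
    njf = np.zeros(n)
    truth_mm = np.zeros((n, 3))
    pred_mm = np.zeros((n, 3))
    gt_targets = []
    ref_target_centroid = ref_masks["target"].centroid_mm()

    for i in range(n):
        gt_masks = sequence.masks_at(i)
        gt_vol = sequence.volume_at(i)
        if isinstance(predictor, Network):
            inputs = _network_inputs(predictor, sequence, i, noise)
            phi = predict_dvf(predictor, inputs)
        else:
            phi = predictor(i, sequence)
        warped = {name: warp_mask(ref_masks[name], phi) for name in names}
        for name in names:
            dsc[name][i] = dice(gt_masks[name], warped[name])
        ce[i] = centroid_error(gt_masks["target"], warped["target"])
        ssim_vals[i] = ssim(gt_vol, warp_volume(ph.reference, phi), mask=ph.thoraco_mask)
        njf[i] = negative_jacobian_fraction(jacobian_determinant(phi))
        truth_mm[i] = gt_masks["target"].centroid_mm() - ref_target_centroid
        pred_mm[i] = warped["target"].centroid_mm() - ref_target_centroid
        gt_targets.append(gt_masks["target"])

    itv = build_itv(gt_targets)
    dyn = build_dynamic_volume(gt_targets, pred_mm)
    mu_itv = itv.centroid_mm()
    itv_ce = np.array([np.linalg.norm(m.centroid_mm() - mu_itv) for m in gt_targets])
    report = MetricsReport(
        dsc=dsc,
        centroid_error_mm=ce,
        ssim=ssim_vals,
        neg_jacobian_fraction=njf,
        itv_volume_mm3=itv.volume_mm3(),
        dynamic_volume_mm3=dyn.volume_mm3(),
        itv_baseline_ce_mm=itv_ce,
    )
    trace = TrackingTrace(time_s=np.asarray(sequence.timestamps_s), truth_mm=truth_mm, predicted_mm=pred_mm)
    return report, trace
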