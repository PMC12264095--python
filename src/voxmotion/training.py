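"""Dataset assembly, the masked-MSE objective, and the optimisation loop.

Training pairs 2D intrafraction-style inputs (projections, slice pairs or
their k-space spectra) with ground-truth DVF labels from the 4D phantom:
for each respiratory bin the reference image supplies the "planning" view
and the bin image the "acquired" view.  Networks are optimised with Adam
on the mean squared DVF error restricted to the thoracoabdominal mask.

Inputs are min/max-scaled to [-1, 1] per input arm using dataset-wide
ranges recorded in the network (and its checkpoint); zero-centred inputs
keep the bias-free first convolutions well conditioned.  A small holdout - every
tenth projection angle, or the first lattice row for slice pairs - is used
for convergence monitoring only; the reference protocol trains on all
views.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .fields import DisplacementField, Mask3D
from .imaging import central_lattice, extract_slices, forward_project, to_kspace
from .networks import ENCODER_LAYOUT, Network, NetworkInputs
from .phantom import Phantom4D

__all__ = [
    "TrainingSample",
    "TrainConfig",
    "Dataset",
    "assemble_xray_dataset",
    "assemble_mri_dataset",
    "masked_mse",
    "train",
]


@dataclass
class TrainingSample:
    """One (inputs, DVF label) pair; ``tag`` is the angle or slice indices."""

    inputs: NetworkInputs
    label: np.ndarray  # (3, D, H, W) mm
    bin_id: int
    tag: tuple
    holdout: bool = False


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (reference protocol defaults)."""

    learning_rate: float = 1e-5
    batch_size: int = 8
    epochs: int = 50
    seed: int = 0
    #: optional weight of a velocity-smoothness prior (0 = pure masked MSE,
    #: the reference objective); used by scaled-down runs to keep predicted
    #: velocities in the smooth regime of the integration layer
    smoothness_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("training hyperparameters must be positive")
        if self.smoothness_weight < 0:
            raise ValueError("smoothness_weight must be non-negative")


@dataclass
class Dataset:
    samples: list[TrainingSample]
    mask: Mask3D
    architecture: str
    #: (lo, hi) per encoding arm, computed over the whole dataset
    input_norm: list[tuple[float, float]] = field(default_factory=list)
    volume_norm: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.samples)

    def train_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.samples) if not s.holdout]

    def holdout_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.samples) if s.holdout]


def _compute_norm(samples: list[TrainingSample], n_arms: int) -> list[tuple[float, float]]:
    norms = []
    for arm in range(n_arms):
        lo = min(float(s.inputs.planes[arm].min()) for s in samples)
        hi = max(float(s.inputs.planes[arm].max()) for s in samples)
        norms.append((lo, hi if hi > lo else lo + 1.0))
    return norms


def assemble_xray_dataset(
    phantom: Phantom4D,
    n_angles: int,
    architecture: str = "A",
    holdout_every: int = 10,
) -> Dataset:
    """Projection dataset: every bin forward-projected at every arc angle.

    Yields ``10 * n_angles`` samples (projecting 10 bins at 630 angles
    gives the protocol's 6300 acquired images).  Variant A concatenates
    reference and acquired projections, B encodes them separately, C pairs
    the acquired projection with the reference volume.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    if architecture not in ("A", "B", "C"):
        raise ValueError("x-ray datasets serve variants A, B and C")
    angles = np.arange(n_angles) * (360.0 / n_angles)
    ref_projs = [forward_project(phantom.reference, a).pixels.astype(np.float32) for a in angles]
    ref_vol = phantom.reference.values.astype(np.float32)
    samples: list[TrainingSample] = []
    for b in range(10):
        label = phantom.dvfs[b].components.astype(np.float32)
        for j, a in enumerate(angles):
            acq = forward_project(phantom.bins[b], a).pixels.astype(np.float32)
            if architecture == "A":
                inputs = NetworkInputs("A", [np.stack([ref_projs[j], acq])])
            elif architecture == "B":
                inputs = NetworkInputs("B", [ref_projs[j][None], acq[None]])
            else:
                inputs = NetworkInputs("C", [acq[None]], volume=ref_vol)
            samples.append(
                TrainingSample(
                    inputs=inputs,
                    label=label,
                    bin_id=b + 1,
                    tag=(float(a),),
                    holdout=(j % holdout_every == 0),
                )
            )
    ds = Dataset(samples, phantom.thoraco_mask, architecture)
    ds.input_norm = _compute_norm(samples, len(ENCODER_LAYOUT[architecture]))
    if architecture == "C":
        ds.volume_norm = (float(ref_vol.min()), float(ref_vol.max()))
    return ds


def assemble_mri_dataset(
    phantom: Phantom4D,
    lattice_k: int = 16,
    architecture: str = "D",
) -> Dataset:
    """Slice-pair dataset on the central k x k (coronal, sagittal) lattice.

    Yields ``10 * k**2`` samples.  Variant D uses the image pairs directly;
    variant E uses the real/imaginary k-space channels of each slice (which
    invert back to the images exactly).  The first lattice row is held out
    for convergence monitoring.
    """
    if architecture not in ("D", "E"):
        raise ValueError("slice-pair datasets serve variants D and E")
    lattice = central_lattice(phantom.grid, lattice_k)
    first_row_c = lattice[0][0]
    samples: list[TrainingSample] = []
    ref_slices = {
        (c, s): extract_slices(phantom.reference, c, s) for (c, s) in lattice
    }
    for b in range(10):
        label = phantom.dvfs[b].components.astype(np.float32)
        for (c, s) in lattice:
            ref = ref_slices[(c, s)]
            acq = extract_slices(phantom.bins[b], c, s)
            if architecture == "D":
                planes = [
                    np.stack([ref.coronal, ref.sagittal]).astype(np.float32),
                    np.stack([acq.coronal, acq.sagittal]).astype(np.float32),
                ]
            else:
                xc = to_kspace(ref.coronal)
                xs = to_kspace(ref.sagittal)
                yc = to_kspace(acq.coronal)
                ys = to_kspace(acq.sagittal)
                planes = [
                    np.stack([xc[0], yc[0]]).astype(np.float32),  # real coronal pair
                    np.stack([xs[0], ys[0]]).astype(np.float32),  # real sagittal pair
                    np.stack([xc[1], yc[1]]).astype(np.float32),  # imag coronal pair
                    np.stack([xs[1], ys[1]]).astype(np.float32),  # imag sagittal pair
                ]
            samples.append(
                TrainingSample(
                    inputs=NetworkInputs(architecture, planes),
                    label=label,
                    bin_id=b + 1,
                    tag=(c, s),
                    holdout=(c == first_row_c),
                )
            )
    ds = Dataset(samples, phantom.thoraco_mask, architecture)
    ds.input_norm = _compute_norm(samples, len(ENCODER_LAYOUT[architecture]))
    return ds


def masked_mse(
    phi: DisplacementField, phi_hat: DisplacementField, mask: Mask3D
) -> float:
    """MSE(phi, phi_hat) within a mask: mean of squared component-wise
    differences over (masked voxels x 3 components), in mm^2."""
    if phi.grid != phi_hat.grid or phi.grid != mask.grid:
        raise ValueError("masked_mse requires a shared grid")
    m = mask.values.astype(bool)
    if not m.any():
        raise ValueError("masked_mse requires a non-empty mask")
    diff = (phi.components - phi_hat.components)[:, m]
    return float((diff**2).mean())


def _batch_arrays(ds: Dataset, net: Network, idx: list[int]):
    n_arms = len(ENCODER_LAYOUT[ds.architecture])
    planes = []
    for arm in range(n_arms):
        lo, hi = ds.input_norm[arm]
        arr = np.stack([ds.samples[i].inputs.planes[arm] for i in idx]).astype(np.float32)
        planes.append(2.0 * (arr - lo) / max(hi - lo, 1e-12) - 1.0)
    vol = None
    if ds.architecture == "C":
        lo, hi = ds.volume_norm
        v = ds.samples[idx[0]].inputs.volume
        vn = 2.0 * (v - lo) / max(hi - lo, 1e-12) - 1.0
        vol = np.repeat(vn[None, None], len(idx), axis=0).astype(np.float32)
    labels = np.stack([ds.samples[i].label for i in idx]).astype(np.float32)
    return planes, vol, labels


def _epoch_loss(net: Network, ds: Dataset, idx: list[int], batch_size: int) -> float:
    """Forward-only masked MSE over ``idx`` in evaluation mode."""
    net.eval()
    total, count = 0.0, 0
    maskf = ds.mask.values.astype(np.float32)
    for start in range(0, len(idx), batch_size):
        chunk = idx[start : start + batch_size]
        planes, vol, labels = _batch_arrays(net=net, ds=ds, idx=chunk)
        pred = net.forward(planes, vol)
        loss = ad.masked_mse_loss(pred, labels, maskf)
        total += float(loss.data) * len(chunk)
        count += len(chunk)
    net.train()
    return total / max(count, 1)


def train(
    net: Network,
    ds: Dataset,
    cfg: TrainConfig,
    out_dir: str | None = None,
    log=None,
) -> list[dict]:
    """Optimise ``net`` on ``ds``; returns the per-epoch loss history.

    Mini-batches are reshuffled each epoch (seed-deterministic).  Epoch 0
    records the pre-training holdout loss.  Best (by holdout loss) and
    final checkpoints are written when ``out_dir`` is given.  Non-finite
    loss aborts with a diagnostic.
    """
    if len(ds) == 0:
        raise ValueError("training requires a non-empty dataset")
    if net.spec.architecture != ds.architecture:
        raise ValueError("network and dataset architecture mismatch")
    rng = np.random.default_rng(cfg.seed)
    net.input_norm = list(ds.input_norm)
    net.volume_norm = ds.volume_norm
    opt = ad.Adam(net.parameters(), lr=cfg.learning_rate)
    maskf = ds.mask.values.astype(np.float32)
    train_idx = ds.train_indices() or list(range(len(ds)))
    val_idx = ds.holdout_indices()

    history: list[dict] = []
    val0 = _epoch_loss(net, ds, val_idx, cfg.batch_size) if val_idx else float("nan")
    history.append({"epoch": 0, "train_loss": float("nan"), "val_loss": val0})
    best = (np.inf, None)
    net.train()
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_idx))
        running, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            chunk = [train_idx[i] for i in order[start : start + cfg.batch_size]]
            planes, vol, labels = _batch_arrays(ds, net, chunk)
            if cfg.smoothness_weight > 0:
                pred, vel = net.forward(planes, vol, return_velocity=True)
                loss = ad.masked_mse_loss(pred, labels, maskf)
                penalty = ad.scale(ad.gradient_penalty(vel), cfg.smoothness_weight)
                loss = ad.add(loss, penalty)
            else:
                pred = net.forward(planes, vol)
                loss = ad.masked_mse_loss(pred, labels, maskf)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite loss); "
                    "lower the learning rate or velocity scale"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            running += float(loss.data) * len(chunk)
            seen += len(chunk)
        val = _epoch_loss(net, ds, val_idx, cfg.batch_size) if val_idx else float("nan")
        row = {"epoch": epoch, "train_loss": running / seen, "val_loss": val}
        history.append(row)
        if log:
            log(row)
        if out_dir is not None and (not np.isnan(val)) and val < best[0]:
            from .networks import save_network

            save_network(net, f"{out_dir}/checkpoint_best")
            best = (val, epoch)
    if out_dir is not None:
        from .networks import save_network

        save_network(net, f"{out_dir}/checkpoint_final")
        with open(f"{out_dir}/loss_history.csv", "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=["epoch", "train_loss", "val_loss"])
            w.writeheader()
            w.writerows(history)
    net.eval()
    return history
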