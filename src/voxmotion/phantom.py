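"""Synthetic 4D thorax phantom with ground-truth diffeomorphic motion.

This module is a self-contained stand-in for licensed 4D anthropomorphic
phantom data.  It provides quasi-periodic breathing traces, a deformable
digital thorax (left-atrium-like target; stomach, esophagus, lungs, spinal
cord as organs-at-risk), amplitude-based respiratory binning into 10 phase
bins, and trace-driven intrafraction sequences over a gantry arc.

Ground-truth motion is generated by scaling a fixed smooth velocity
template by the instantaneous breathing amplitude and integrating it with
the same scaling-and-squaring operator used at the network output, so all
ground-truth deformations are diffeomorphic by construction and every label
is exactly reproducible from the stored velocity template.  Inhalation
moves the diaphragm inferiorly with a coupled anterior component; the
motion magnitude decays superiorly from the diaphragm plane and vanishes at
the spinal cord.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.spatial import ConvexHull

from .fields import (
    DisplacementField,
    Grid3,
    Mask3D,
    VelocityField,
    Volume3D,
    integrate_velocity,
    jacobian_determinant,
    negative_jacobian_fraction,
    warp_mask,
    warp_volume,
)

__all__ = [
    "BreathingTrace",
    "AnatomyConfig",
    "Phantom4D",
    "IntrafractionSequence",
    "generate_trace",
    "bin_trace",
    "build_anatomy",
    "build_phantom",
    "make_thoraco_mask",
    "simulate_intrafraction",
    "save_phantom",
    "load_phantom",
]

STRUCTURES = ("target", "stomach", "esophagus", "left_lung", "right_lung", "spinal_cord")

#: per-structure intensities for the two imaging contrasts
XRAY_INTENSITY = {
    "body": 1.0,
    "target": 1.15,
    "stomach": 0.55,
    "esophagus": 0.9,
    "left_lung": 0.18,
    "right_lung": 0.18,
    "spinal_cord": 1.6,
}
MR_INTENSITY = {
    "body": 0.55,
    "target": 1.0,
    "stomach": 0.85,
    "esophagus": 0.7,
    "left_lung": 0.08,
    "right_lung": 0.08,
    "spinal_cord": 0.35,
}


@dataclass
class BreathingTrace:
    """Respiratory surrogate trace, 0 = peak exhale, 1 = nominal peak inhale.

    Cycle-to-cycle amplitude/period jitter and drift can push samples
    slightly above 1 (bounded at 1.2).  ``amplitude_mm`` is the peak
    diaphragm excursion the trace drives (5 and 10 mm presets bracket the
    clinically observed range).
    """

    samples: np.ndarray
    rate_hz: float
    period_s: float
    amplitude_mm: float
    amplitude_jitter: float = 0.0
    period_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate_hz <= 0 or self.period_s <= 0:
            raise ValueError("rate and period must be positive")
        if self.samples.min() < 0 or self.samples.max() > 1.2:
            raise ValueError("trace samples must lie in [0, 1.2]")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate_hz


def generate_trace(
    duration_s: float,
    rate_hz: float = 10.5,
    period_s: float = 4.0,
    amplitude_mm: float = 10.0,
    amplitude_jitter: float = 0.0,
    period_jitter: float = 0.0,
    cardiac_fraction: float = 0.0,
    cardiac_rate_hz: float = 1.2,
    sharpness: int = 2,
    seed: int = 0,
) -> BreathingTrace:
    """Generate a quasi-periodic breathing trace.

    Each cycle has shape ``sin(pi t / tau) ** (2 * sharpness)`` which dwells
    near exhale, with per-cycle amplitude and period drawn from Gaussian
    jitter around the nominal values.  An optional small additive
    high-frequency cardiac component is off by default.  Deterministic
    under ``seed``.
    """
    if duration_s <= 0 or rate_hz <= 0 or period_s <= 0:
        raise ValueError("duration, rate and period must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    samples = np.empty(n)
    t0 = 0.0
    i = 0
    while i < n:
        tau = period_s * max(0.2, 1.0 + period_jitter * rng.standard_normal())
        amp = max(0.0, 1.0 + amplitude_jitter * rng.standard_normal())
        in_cycle = (t >= t0) & (t < t0 + tau)
        phase = (t[in_cycle] - t0) / tau
        samples[in_cycle] = amp * np.sin(np.pi * phase) ** (2 * sharpness)
        i += int(in_cycle.sum())
        t0 += tau
    if cardiac_fraction > 0:
        samples = samples + cardiac_fraction * 0.5 * (1 + np.sin(2 * np.pi * cardiac_rate_hz * t))
    samples = np.clip(samples, 0.0, 1.2)
    return BreathingTrace(
        samples,
        rate_hz=rate_hz,
        period_s=period_s,
        amplitude_mm=amplitude_mm,
        amplitude_jitter=amplitude_jitter,
        period_jitter=period_jitter,
        seed=seed,
    )


def bin_trace(trace: BreathingTrace, n_bins: int = 10) -> np.ndarray:
    """Amplitude-based respiratory binning into equal-width bands.

    Bin 1 is the peak-exhale band.  Ties on a band edge break toward the
    lower bin.  A constant trace puts every sample in bin 1.
    """
    if n_bins < 2:
        raise ValueError("binning requires n_bins >= 2")
    a = trace.samples
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return np.ones(len(a), dtype=np.int64)
    edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
    # side='left': a sample exactly on an edge joins the lower bin
    return np.searchsorted(edges, a, side="left").astype(np.int64) + 1


@dataclass
class AnatomyConfig:
    """Geometry and contrast of the digital thorax.

    Structure centres and radii are stored as fractions of the field of
    view so one configuration scales across grid resolutions; they are
    resolved to mm against ``grid``.  ``mode`` selects the x-ray or MR
    intensity table.
    """

    grid: Grid3 = field(default_factory=lambda: Grid3((64, 64, 64), (4.0, 4.0, 4.0)))
    mode: str = "xray"  # "xray" | "mr"
    diaphragm_si_frac: float = 0.38
    decay_si_frac: float = 0.60  # decay length of motion above the diaphragm
    ap_coupling: float = 0.4  # anterior motion per unit inferior motion
    seed: int = 0

    def intensity(self, name: str) -> float:
        table = XRAY_INTENSITY if self.mode == "xray" else MR_INTENSITY
        return table[name]


def _ellipsoid(grid: Grid3, center_frac, radii_frac) -> np.ndarray:
    lr, ap, si = grid.voxel_coords()
    n = np.asarray(grid.shape)
    c = np.asarray(center_frac) * (n - 1)
    r = np.maximum(np.asarray(radii_frac) * n, 1.0)
    d = ((lr - c[0]) / r[0]) ** 2 + ((ap - c[1]) / r[1]) ** 2 + ((si - c[2]) / r[2]) ** 2
    return d <= 1.0


def build_anatomy(cfg: AnatomyConfig) -> tuple[Volume3D, dict[str, Mask3D]]:
    """Rasterise the reference (peak-exhale) thorax and its structure masks."""
    g = cfg.grid
    body = _ellipsoid(g, (0.5, 0.5, 0.5), (0.44, 0.40, 0.55))
    masks = {
        # left-atrium-like target: mid-thorax, slightly left of midline
        "target": _ellipsoid(g, (0.58, 0.42, 0.60), (0.105, 0.10, 0.10)),
        "stomach": _ellipsoid(g, (0.62, 0.52, 0.24), (0.14, 0.12, 0.11)),
        "esophagus": _ellipsoid(g, (0.50, 0.56, 0.55), (0.035, 0.035, 0.30)),
        "left_lung": _ellipsoid(g, (0.68, 0.48, 0.62), (0.14, 0.22, 0.24)),
        "right_lung": _ellipsoid(g, (0.30, 0.48, 0.62), (0.15, 0.23, 0.25)),
        "spinal_cord": _ellipsoid(g, (0.50, 0.74, 0.50), (0.04, 0.04, 0.36)),
    }
    # carve target and esophagus out of the lungs so structures are disjoint
    for lung in ("left_lung", "right_lung"):
        masks[lung] &= ~(masks["target"] | masks["esophagus"])
    values = np.where(body, cfg.intensity("body"), 0.0)
    for name in ("left_lung", "right_lung", "stomach", "esophagus", "spinal_cord", "target"):
        values = np.where(masks[name], cfg.intensity(name), values)
    values = gaussian_filter(values, sigma=0.8)
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"structure {name} is empty on this grid")
        if not (m <= body).all():
            raise ValueError(f"structure {name} extends outside the body outline")
    vol = Volume3D(g, values)
    return vol, {k: Mask3D(g, v.astype(np.uint8)) for k, v in masks.items()}


def _velocity_template(cfg: AnatomyConfig, cord: Mask3D) -> VelocityField:
    """Smooth unit velocity template for one unit (mm) of diaphragm excursion.

    Dominant SI component directed superiorly in the DVF frame (so that the
    backward-warped anatomy shifts inferiorly during inhale), magnitude ~1
    at/below the diaphragm plane, decaying superiorly with length
    ``decay_si_frac`` and suppressed to zero at the spinal cord; a coupled
    anterior component of relative size ``ap_coupling``.
    """
    g = cfg.grid
    lr, ap, si = g.voxel_coords()
    n = np.asarray(g.shape)
    z_dia = cfg.diaphragm_si_frac * (n[2] - 1)
    decay = max(cfg.decay_si_frac * n[2], 2.0)
    # full motion at/below the diaphragm, Gaussian decay superiorly; the
    # decay length is long relative to the target so the (cardiac) target
    # translates quasi-rigidly rather than compressing
    height = np.maximum(si - z_dia, 0.0)
    w = np.exp(-((height / decay) ** 4))
    # suppress motion around the spinal cord with a gentle shoulder so the
    # ground-truth fields stay far from folding
    cord_idx = np.argwhere(cord.values > 0)
    c_lr, c_ap = cord_idx[:, 0].mean(), cord_idx[:, 1].mean()
    sigma_r = 0.16 * n[:2].mean()
    d2 = ((lr - c_lr) ** 2 + (ap - c_ap) ** 2) / sigma_r**2
    w = w * (1.0 - np.exp(-d2))
    w = gaussian_filter(w, sigma=1.5)
    w /= max(w.max(), 1e-12)
    comps = np.zeros((3,) + g.shape)
    comps[2] = w  # + SI: backward sampling pulls from superior -> anatomy moves inferior
    comps[1] = -cfg.ap_coupling * w  # - AP: anatomy moves anterior
    return VelocityField(g, comps)


@dataclass
class Phantom4D:
    """10-bin synthetic 4D scan with ground-truth DVFs and structure masks."""

    reference: Volume3D
    bins: list[Volume3D]
    dvfs: list[DisplacementField]
    structures: list[dict[str, Mask3D]]  # per bin
    reference_structures: dict[str, Mask3D]
    thoraco_mask: Mask3D
    velocity_template: VelocityField
    bin_amplitudes: np.ndarray
    amplitude_mm: float
    anatomy: AnatomyConfig
    integration_steps: int = 10

    def __post_init__(self) -> None:
        if len(self.bins) != 10 or len(self.dvfs) != 10:
            raise ValueError("a phantom has exactly 10 respiratory bins")
        if self.dvfs[0].max_magnitude_mm() > 1e-9:
            raise ValueError("the reference (peak-exhale) bin DVF must be identity")

    @property
    def grid(self) -> Grid3:
        return self.reference.grid

    def dvf_for_amplitude(self, a: float) -> DisplacementField:
        """Ground-truth DVF for a continuous trace amplitude in [0, 1.2]."""
        u = VelocityField(self.grid, self.velocity_template.components * (a * self.amplitude_mm))
        phi = integrate_velocity(u, self.integration_steps)
        phi.provenance = "ground_truth"
        return phi

    def volume_for_amplitude(self, a: float) -> Volume3D:
        return warp_volume(self.reference, self.dvf_for_amplitude(a))

    def masks_for_amplitude(self, a: float) -> dict[str, Mask3D]:
        phi = self.dvf_for_amplitude(a)
        return {k: warp_mask(m, phi) for k, m in self.reference_structures.items()}


def make_thoraco_mask(
    left_lung: Mask3D,
    right_lung: Mask3D,
    dilation_mm: float = 8.0,
    grid: Grid3 | None = None,
) -> Mask3D:
    """Thoracoabdominal loss mask from the lung masks.

    Convex hull of the union of both lungs, binary dilation by
    ``dilation_mm``, then extension inferiorly to the bottom of the image
    within the (LR, AP) footprint of the hull.
    """
    grid = grid or left_lung.grid
    union = (left_lung.values | right_lung.values).astype(bool)
    if not union.any():
        raise ValueError("thoracoabdominal mask requires non-empty lungs")
    # rasterise the convex hull of the union: voxel centres on or inside
    # every facet half-space
    pts = np.argwhere(union)
    try:
        facets = ConvexHull(pts).equations
        coords = np.stack(grid.voxel_coords(), axis=-1).reshape(-1, 3)
        inside = (coords @ facets[:, :3].T + facets[:, 3]) <= 1e-9
        hull = inside.all(axis=1).reshape(grid.shape)
    except Exception:  # degenerate (coplanar) point sets
        hull = union.copy()
    if dilation_mm > 0:
        r = np.maximum(np.round(dilation_mm / np.asarray(grid.spacing)).astype(int), 0)
        if r.max() > 0:
            zyx = np.ogrid[-r[0]:r[0] + 1, -r[1]:r[1] + 1, -r[2]:r[2] + 1]
            ball = sum((z / max(rr, 1)) ** 2 for z, rr in zip(zyx, r)) <= 1.0
            hull = binary_dilation(hull, structure=ball)
    footprint = hull.any(axis=2)  # (LR, AP) columns touched by the hull
    lowest = np.where(hull, np.arange(grid.shape[2])[None, None, :], grid.shape[2]).min(axis=2)
    out = hull.copy()
    si = np.arange(grid.shape[2])[None, None, :]
    out |= footprint[:, :, None] & (si <= lowest[:, :, None])
    return Mask3D(grid, out.astype(np.uint8))


def build_phantom(
    anatomy: AnatomyConfig,
    trace: BreathingTrace,
    n_bins: int = 10,
    integration_steps: int = 10,
) -> Phantom4D:
    """Build the 10-bin 4D phantom driven by a breathing trace.

    Each bin's representative amplitude is the mean trace amplitude within
    the bin, shifted so the peak-exhale bin (bin 1) is exactly the
    reference.  Ground-truth DVFs are obtained by scaling the velocity
    template by ``amplitude * amplitude_mm`` and integrating; bin volumes
    and per-bin structure masks are backward-warped from the reference.
    """
    reference, structures = build_anatomy(anatomy)
    labels = bin_trace(trace, n_bins)
    reps = np.zeros(n_bins)
    for b in range(1, n_bins + 1):
        sel = labels == b
        reps[b - 1] = trace.samples[sel].mean() if sel.any() else np.nan
    # empty bins inherit the nominal band centre
    if np.isnan(reps).any():
        centers = (np.arange(n_bins) + 0.5) / n_bins * (trace.samples.max() - trace.samples.min())
        reps = np.where(np.isnan(reps), trace.samples.min() + centers, reps)
    reps = reps - reps[0]  # bin 1 (peak exhale) is the reference: identity DVF

    template = _velocity_template(anatomy, structures["spinal_cord"])
    bins: list[Volume3D] = []
    dvfs: list[DisplacementField] = []
    per_bin_masks: list[dict[str, Mask3D]] = []
    for b in range(n_bins):
        u = VelocityField(anatomy.grid, template.components * (reps[b] * trace.amplitude_mm))
        phi = integrate_velocity(u, integration_steps)
        phi.provenance = "ground_truth"
        frac = negative_jacobian_fraction(jacobian_determinant(phi))
        half_fov = 0.5 * min(anatomy.grid.extent_mm)
        if frac > 0 or phi.max_magnitude_mm() > half_fov:
            raise ValueError(
                f"bin {b + 1} ground-truth DVF is not usable (negative-Jacobian fraction "
                f"{frac:.3g}, max displacement {phi.max_magnitude_mm():.1f} mm on a "
                f"{2 * half_fov:.0f} mm field of view); reduce amplitude_mm"
            )
        dvfs.append(phi)
        bins.append(warp_volume(reference, phi))
        per_bin_masks.append({k: warp_mask(m, phi) for k, m in structures.items()})
    thoraco = make_thoraco_mask(structures["left_lung"], structures["right_lung"], grid=anatomy.grid)
    return Phantom4D(
        reference=reference,
        bins=bins,
        dvfs=dvfs,
        structures=per_bin_masks,
        reference_structures=structures,
        thoraco_mask=thoraco,
        velocity_template=template,
        bin_amplitudes=reps,
        amplitude_mm=trace.amplitude_mm,
        anatomy=anatomy,
        integration_steps=integration_steps,
    )


@dataclass
class IntrafractionSequence:
    """Trace-driven intrafraction imaging sequence over a gantry arc.

    Volumes, DVFs and masks are generated on demand from the phantom's
    continuously scaled velocity template (or snapped to the nearest of the
    10 bins when ``bin_snapped``), one per timestamp, with the gantry angle
    sweeping the arc linearly.
    """

    phantom: Phantom4D
    timestamps_s: np.ndarray
    amplitudes: np.ndarray
    angles_deg: np.ndarray
    bin_snapped: bool = False

    def __len__(self) -> int:
        return len(self.timestamps_s)

    def _effective_amplitude(self, i: int) -> float:
        a = float(self.amplitudes[i])
        if self.bin_snapped:
            j = int(np.argmin(np.abs(self.phantom.bin_amplitudes - a)))
            return float(self.phantom.bin_amplitudes[j])
        return a

    def dvf_at(self, i: int) -> DisplacementField:
        return self.phantom.dvf_for_amplitude(self._effective_amplitude(i))

    def volume_at(self, i: int) -> Volume3D:
        a = self._effective_amplitude(i)
        if self.bin_snapped:
            j = int(np.argmin(np.abs(self.phantom.bin_amplitudes - a)))
            return self.phantom.bins[j]
        return self.phantom.volume_for_amplitude(a)

    def masks_at(self, i: int) -> dict[str, Mask3D]:
        a = self._effective_amplitude(i)
        if self.bin_snapped:
            j = int(np.argmin(np.abs(self.phantom.bin_amplitudes - a)))
            return self.phantom.structures[j]
        return self.phantom.masks_for_amplitude(a)


def simulate_intrafraction(
    phantom: Phantom4D,
    trace: BreathingTrace,
    arc_start_deg: float = 0.0,
    arc_span_deg: float = 360.0,
    bin_snapped: bool = False,
) -> IntrafractionSequence:
    """Pair each trace sample with a gantry angle spanning the arc linearly."""
    n = len(trace.samples)
    if n < 2:
        raise ValueError("intrafraction simulation requires at least 2 trace samples")
    angles = (arc_start_deg + np.arange(n) * (arc_span_deg / n)) % 360.0
    # shift trace so its minimum matches the phantom reference (peak exhale)
    amplitudes = trace.samples - phantom.bin_amplitudes.min()
    return IntrafractionSequence(
        phantom=phantom,
        timestamps_s=trace.times_s,
        amplitudes=amplitudes,
        angles_deg=angles,
        bin_snapped=bin_snapped,
    )


# ---------------------------------------------------------------------------
# HDF5 phantom bundle

def save_phantom(path: str, phantom: Phantom4D) -> None:
    """Export the phantom bundle (volumes, DVFs, masks, template) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        g = phantom.grid
        f.attrs["shape"] = g.shape
        f.attrs["spacing"] = g.spacing
        f.attrs["origin"] = g.origin
        f.attrs["amplitude_mm"] = phantom.amplitude_mm
        f.attrs["integration_steps"] = phantom.integration_steps
        f.attrs["mode"] = phantom.anatomy.mode
        f["reference"] = phantom.reference.values
        f["velocity_template"] = phantom.velocity_template.components
        f["bin_amplitudes"] = phantom.bin_amplitudes
        f["thoraco_mask"] = phantom.thoraco_mask.values
        for b in range(10):
            f[f"bins/{b}"] = phantom.bins[b].values
            f[f"dvfs/{b}"] = phantom.dvfs[b].components
            for k, m in phantom.structures[b].items():
                f[f"masks/{b}/{k}"] = m.values
        for k, m in phantom.reference_structures.items():
            f[f"reference_masks/{k}"] = m.values


def load_phantom(path: str) -> Phantom4D:
    import h5py

    with h5py.File(path, "r") as f:
        grid = Grid3(tuple(f.attrs["shape"]), tuple(f.attrs["spacing"]), tuple(f.attrs["origin"]))
        anatomy = AnatomyConfig(grid=grid, mode=str(f.attrs["mode"]))
        ref = Volume3D(grid, f["reference"][()])
        template = VelocityField(grid, f["velocity_template"][()])
        reps = f["bin_amplitudes"][()]
        thoraco = Mask3D(grid, f["thoraco_mask"][()])
        bins, dvfs, structures = [], [], []
        for b in range(10):
            bins.append(Volume3D(grid, f[f"bins/{b}"][()]))
            dvfs.append(DisplacementField(grid, f[f"dvfs/{b}"][()], provenance="ground_truth"))
            structures.append(
                {k: Mask3D(grid, f[f"masks/{b}/{k}"][()]) for k in f[f"masks/{b}"].keys()}
            )
        ref_masks = {k: Mask3D(grid, f[f"reference_masks/{k}"][()]) for k in f["reference_masks"].keys()}
        return Phantom4D(
            reference=ref,
            bins=bins,
            dvfs=dvfs,
            structures=structures,
            reference_structures=ref_masks,
            thoraco_mask=thoraco,
            velocity_template=template,
            bin_amplitudes=reps,
            amplitude_mm=float(f.attrs["amplitude_mm"]),
            anatomy=anatomy,
            integration_steps=int(f.attrs["integration_steps"]),
        )
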