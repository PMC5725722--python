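"""Synthetic MEG generator: sources, forward model, anatomy perturbation.

Everything downstream (beamforming, connectivity, network statistics, the
consistency layer) is exercised on data produced here. The generator emulates
a resting-state atlas-based MEG study:

* cortical regions of interest (ROIs), each a small patch of source voxels on
  a 2 mm grid inside a spherical volume conductor;
* narrowband oscillatory ROI signals with configurable constant-phase-lag
  coupling between ROI pairs in the classical frequency bands;
* a whole-head axial sensor array on a hemisphere above the conductor;
* the Sarvas closed-form forward field of a current dipole in a homogeneous
  conducting sphere;
* a second, "template" anatomy in which voxel positions are displaced by a
  configurable magnitude, emulating template-vs-native MRI co-registration
  mismatch.

All operations are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .bands import BandDefinition, CLASSICAL_BANDS, band_by_name, check_contiguous

__all__ = [
    "Conductor",
    "SensorArray",
    "Coupling",
    "SourceModel",
    "EpochSet",
    "LeadFieldMatrix",
    "spiral_sensor_array",
    "generate_sources",
    "compute_leadfield",
    "perturb_anatomy",
    "project_to_sensors",
    "narrowband_noise",
    "phase_shifted_copy",
]


# ---------------------------------------------------------------------------
# geometry containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Conductor:
    """Homogeneous spherical volume conductor (mm, head frame)."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 90.0

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(points) - np.asarray(self.center)
        return np.linalg.norm(pts, axis=-1) < self.radius - margin


@dataclass
class SensorArray:
    """Point magnetometer array: positions (mm) and unit orientations."""

    channel_positions: np.ndarray    # (M, 3)
    channel_orientations: np.ndarray  # (M, 3), unit norm

    def __post_init__(self) -> None:
        self.channel_positions = np.asarray(self.channel_positions, float)
        self.channel_orientations = np.asarray(self.channel_orientations, float)
        if self.channel_positions.shape != self.channel_orientations.shape:
            raise ValueError("positions/orientations shape mismatch")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        norms = np.linalg.norm(self.channel_orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("channel orientations must be unit vectors")

    @property
    def n_channels(self) -> int:
        return self.channel_positions.shape[0]

    def validate_outside(self, conductor: Conductor) -> None:
        if np.any(self.contains_any(conductor)):
            raise ValueError("all channels must lie strictly outside the conductor")

    def contains_any(self, conductor: Conductor) -> np.ndarray:
        return conductor.contains(self.channel_positions)


def spiral_sensor_array(
    n_channels: int = 151,
    conductor: Conductor = Conductor(),
    radius_factor: float = 1.1,
) -> SensorArray:
    """Quasi-uniform Fibonacci spiral on the upper hemisphere.

    A generic stand-in for a whole-head axial system: channels sit at
    ``radius_factor`` times the conductor radius, oriented radially.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    k = np.arange(n_channels)
    golden = (1 + 5 ** 0.5) / 2
    # z from just above the equator to the pole, spiral in azimuth
    z = 0.05 + (1.0 - 0.05) * (k + 0.5) / n_channels
    phi = 2 * np.pi * k / golden
    rho = np.sqrt(np.clip(1 - z ** 2, 0, None))
    dirs = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    r = radius_factor * conductor.radius
    pos = np.asarray(conductor.center) + r * dirs
    return SensorArray(pos, dirs)


# ---------------------------------------------------------------------------
# source model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Coupling:
    """Constant-phase-lag coupling between two ROIs within one band."""

    roi_i: int
    roi_j: int
    band: str
    phase_lag: float            # rad, in (-pi, pi]
    strength: float             # in [0, 1]

    def __post_init__(self) -> None:
        if not (-np.pi < self.phase_lag <= np.pi):
            raise ValueError("phase lag must lie in (-pi, pi]")
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("coupling strength must lie in [0, 1]")


@dataclass
class SourceModel:
    """Ground-truth source space: geometry, ROI labels, coupling, time series.

    ``series`` holds one broadband time series per voxel (all voxels of a ROI
    share the ROI signal), sampled at ``fs``.
    """

    positions: np.ndarray        # (V, 3) mm, head frame
    orientations: np.ndarray     # (V, 3) unit vectors
    roi_labels: np.ndarray       # (V,) int, 1..R
    series: np.ndarray           # (V, n_samples)
    fs: float
    coupling: tuple[Coupling, ...] = ()
    band_defs: tuple[BandDefinition, ...] = CLASSICAL_BANDS
    conductor: Conductor = field(default_factory=Conductor)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.orientations = np.asarray(self.orientations, float)
        self.roi_labels = np.asarray(self.roi_labels, int)
        self.series = np.asarray(self.series, float)
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must have unit norm")
        if self.roi_labels.min(initial=1) < 1:
            raise ValueError("roi labels start at 1")
        check_contiguous(self.band_defs)
        counts = np.bincount(self.roi_labels)
        if np.any(counts[1:] == 0) and len(counts) > 1:
            raise ValueError("every ROI must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    @property
    def n_rois(self) -> int:
        return int(self.roi_labels.max())

    @property
    def n_samples(self) -> int:
        return self.series.shape[1]

    def roi_voxels(self, roi: int) -> np.ndarray:
        """Voxel indices (0-based) belonging to ROI ``roi`` (1-based label)."""
        return np.flatnonzero(self.roi_labels == roi)


@dataclass
class EpochSet:
    """Sensor-space epochs: channels x samples x epochs."""

    data: np.ndarray
    fs: float
    condition_tag: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x samples x epochs")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        """Duration of one epoch in seconds."""
        return self.epoch_len / self.fs

    def validate_bands(self, bands: Sequence[BandDefinition]) -> None:
        top = max(b.f_high for b in bands)
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge {top}"
            )

    def concatenated(self) -> np.ndarray:
        """Channels x (samples*epochs), epochs in order."""
        return self.data.transpose(0, 2, 1).reshape(self.n_channels, -1)


@dataclass
class LeadFieldMatrix:
    """Forward operator for one voxel: channels x 3 (vector) or channels (scalar)."""

    entries: np.ndarray
    voxel_id: int
    conductor: Conductor

    @property
    def is_scalar(self) -> bool:
        return self.entries.ndim == 1


# ---------------------------------------------------------------------------
# signal construction
# ---------------------------------------------------------------------------

def narrowband_noise(
    n_samples: int, band: BandDefinition, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise brick-wall filtered to ``band``.

    White Gaussian noise is FFT-filtered with a hard mask on ``[f_low, f_high)``
    (both frequency signs), then standardized.
    """
    band.validate_for_fs(fs)
    x = rng.standard_normal(n_samples)
    spec = np.fft.fft(x)
    f = np.abs(np.fft.fftfreq(n_samples, 1.0 / fs))
    mask = (f >= band.f_low) & (f < band.f_high)
    spec[~mask] = 0.0
    y = np.fft.ifft(spec).real
    sd = y.std()
    if sd == 0:
        raise ValueError(f"band {band.name!r} contains no FFT bins at n={n_samples}")
    return y / sd


def phase_shifted_copy(x: np.ndarray, lag: float) -> np.ndarray:
    """Copy of narrowband ``x`` whose instantaneous phase trails by ``lag`` rad.

    The analytic signal is rotated by ``exp(-i*lag)`` so that
    ``phase(x) - phase(result) = lag`` at every sample.
    """
    return np.real(hilbert(x) * np.exp(-1j * lag))


def generate_sources(
    n_rois: int,
    voxels_per_roi: int,
    n_samples: int,
    fs: float,
    couplings: Sequence[Coupling] = (),
    bands: Sequence[BandDefinition] = CLASSICAL_BANDS,
    conductor: Conductor = Conductor(),
    seed: int = 0,
    grid_mm: float = 2.0,
) -> SourceModel:
    """Generate the ground-truth source model.

    ROI centers sit on a quasi-uniform hemisphere shell inside the conductor;
    each ROI is a compact patch of ``voxels_per_roi`` voxels on a ``grid_mm``
    grid. Every ROI carries a unit-variance narrowband component in every
    band; for each configured coupling, the partner ROI's component in that
    band is ``strength * phase-shifted copy + (1 - strength) * independent
    noise``, re-standardized, so strength 1 yields a pure constant-lag copy
    and strength 0 yields independence.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    if voxels_per_roi < 1:
        raise ValueError("voxels_per_roi must be >= 1")
    check_contiguous(bands)
    band_names = {b.name for b in bands}
    for c in couplings:
        if c.band not in band_names:
            raise ValueError(f"coupling references unknown band {c.band!r}")
        for roi in (c.roi_i, c.roi_j):
            if not (1 <= roi <= n_rois):
                raise ValueError(f"coupling references unknown ROI {roi}")

    rng = np.random.default_rng(seed)

    # --- geometry: ROI centers on a hemispherical shell -------------------
    k = np.arange(n_rois)
    golden = (1 + 5 ** 0.5) / 2
    z = 0.15 + 0.75 * (k + 0.5) / n_rois
    phi = 2 * np.pi * k / golden
    rho = np.sqrt(np.clip(1 - z ** 2, 0, None))
    dirs = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = rng.uniform(0.50, 0.72, size=n_rois) * conductor.radius
    centers = np.asarray(conductor.center) + radii[:, None] * dirs

    # compact voxel patch per ROI: nearest offsets on the grid
    span = np.arange(-2, 3)
    offsets = np.stack(np.meshgrid(span, span, span, indexing="ij"), -1).reshape(-1, 3)
    order = np.argsort(np.linalg.norm(offsets, axis=1), kind="stable")
    patch = offsets[order[:voxels_per_roi]] * grid_mm

    positions = (centers[:, None, :] + patch[None, :, :]).reshape(-1, 3)
    roi_labels = np.repeat(np.arange(1, n_rois + 1), voxels_per_roi)
    if not np.all(conductor.contains(positions, margin=1.0)):
        raise ValueError("generated voxels fall outside the conductor")

    # tangential orientations (radial dipoles are magnetically silent)
    center = np.asarray(conductor.center)
    radial = positions - center
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    raw = rng.standard_normal((positions.shape[0], 3))
    raw -= (np.sum(raw * radial, axis=1, keepdims=True)) * radial
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    # degenerate draws (norm ~ 0) are vanishingly rare; re-seeded draw
    while np.any(norms < 1e-9):
        bad = norms[:, 0] < 1e-9
        raw[bad] = rng.standard_normal((bad.sum(), 3))
        raw[bad] -= np.sum(raw[bad] * radial[bad], axis=1, keepdims=True) * radial[bad]
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
    orientations = raw / norms

    # --- band-limited ROI signals -----------------------------------------
    comp: dict[str, np.ndarray] = {}
    for band in bands:
        comp[band.name] = np.stack(
            [narrowband_noise(n_samples, band, fs, rng) for _ in range(n_rois)]
        )
    for c in couplings:
        band = band_by_name(c.band, bands)
        src = comp[c.band][c.roi_i - 1]
        indep = narrowband_noise(n_samples, band, fs, rng)
        mixed = c.strength * phase_shifted_copy(src, c.phase_lag) + (1 - c.strength) * indep
        sd = mixed.std()
        if sd > 0:
            mixed = mixed / sd
        comp[c.band][c.roi_j - 1] = mixed

    roi_series = np.zeros((n_rois, n_samples))
    for band in bands:
        roi_series += comp[band.name]
    series = roi_series[roi_labels - 1]

    return SourceModel(
        positions=positions,
        orientations=orientations,
        roi_labels=roi_labels,
        series=series,
        fs=fs,
        coupling=tuple(couplings),
        band_defs=tuple(bands),
        conductor=conductor,
    )


# ---------------------------------------------------------------------------
# forward model (Sarvas)
# ---------------------------------------------------------------------------

_MU0_4PI = 1e-7  # T·m/A; absolute scale is irrelevant downstream


def _sarvas_field(r0: np.ndarray, q: np.ndarray, sensors_pos: np.ndarray,
                  center: np.ndarray) -> np.ndarray:
    """Magnetic field (M, 3) of current dipole q at r0 inside a sphere.

    Closed-form solution for a homogeneous spherical conductor; positions in
    mm are converted to meters so the output carries physical field units.
    """
    r0 = (np.asarray(r0, float) - center) * 1e-3
    r = (np.asarray(sensors_pos, float) - center) * 1e-3
    q = np.asarray(q, float)

    a_vec = r - r0                                  # (M, 3)
    a = np.linalg.norm(a_vec, axis=1)               # |r - r0|
    rn = np.linalg.norm(r, axis=1)                  # |r|
    ar = np.einsum("ij,ij->i", a_vec, r)            # (r - r0) · r
    f = a * (rn * a + rn ** 2 - np.einsum("j,ij->i", r0, r))
    grad_f = (
        (a ** 2 / rn + ar / a + 2 * a + 2 * rn)[:, None] * r
        - (a + 2 * rn + ar / a)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)                          # (3,)
    num = f[:, None] * qxr0[None, :] - np.einsum("j,ij->i", qxr0, r)[:, None] * grad_f
    return _MU0_4PI * num / (f ** 2)[:, None]


def compute_leadfield(
    position: np.ndarray,
    orientation: np.ndarray | None,
    sensors: SensorArray,
    conductor: Conductor = Conductor(),
) -> LeadFieldMatrix:
    """Lead field of a dipole in a homogeneous sphere at each channel.

    With ``orientation`` given (unit 3-vector) the result is scalar mode
    (one value per channel); with ``orientation=None`` it is vector mode
    (channels x 3, columns = unit dipoles along x, y, z). Channel values are
    the Sarvas field projected onto the channel orientation.
    """
    position = np.asarray(position, float)
    center = np.asarray(conductor.center, float)
    rad = np.linalg.norm(position - center)
    if rad >= conductor.radius:
        raise ValueError("dipole position must lie strictly inside the conductor")
    if rad < 1e-9:
        raise ValueError("degenerate geometry: dipole at sphere center")
    sensors.validate_outside(conductor)

    def scalar_lf(q: np.ndarray) -> np.ndarray:
        b = _sarvas_field(position, q, sensors.channel_positions, center)
        return np.einsum("ij,ij->i", b, sensors.channel_orientations)

    if orientation is None:
        cols = [scalar_lf(e) for e in np.eye(3)]
        entries = np.stack(cols, axis=1)
    else:
        orientation = np.asarray(orientation, float)
        entries = scalar_lf(orientation)
    return LeadFieldMatrix(entries=entries, voxel_id=-1, conductor=conductor)


# ---------------------------------------------------------------------------
# anatomy perturbation ("template" condition)
# ---------------------------------------------------------------------------

def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    while np.any(norms < 1e-12):
        bad = norms[:, 0] < 1e-12
        v[bad] = rng.standard_normal((bad.sum(), 3))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
    return v / norms


def perturb_anatomy(
    model: SourceModel,
    displacement_mm: float,
    mode: str = "per_voxel",
    seed: int = 0,
) -> SourceModel:
    """Displace source geometry, emulating template-MRI co-registration error.

    ``per_voxel``: each voxel moves ``displacement_mm`` along an independent
    uniformly random direction (re-drawn up to 100 times if it would leave the
    conductor). ``rigid``: a single random translation of that magnitude plus
    a small random rotation about the conductor center. Time series, labels
    and coupling are untouched.
    """
    if displacement_mm < 0:
        raise ValueError("displacement must be >= 0")
    if mode not in ("per_voxel", "rigid"):
        raise ValueError(f"unknown mode {mode!r}")
    if displacement_mm == 0:
        return replace(model, positions=model.positions.copy())

    rng = np.random.default_rng(seed)
    cond = model.conductor
    if mode == "per_voxel":
        new_pos = model.positions.copy()
        for v in range(model.n_voxels):
            ok = False
            for _ in range(100):
                d = _random_unit_vectors(1, rng)[0]
                cand = model.positions[v] + displacement_mm * d
                if cond.contains(cand[None, :], margin=0.5)[0]:
                    new_pos[v] = cand
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"voxel {v} cannot be displaced {displacement_mm} mm "
                    "without leaving the conductor"
                )
    else:
        t = displacement_mm * _random_unit_vectors(1, rng)[0]
        axis = _random_unit_vectors(1, rng)[0]
        angle = displacement_mm / cond.radius  # rad: comparable surface motion
        K = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        rot = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        center = np.asarray(cond.center)
        new_pos = (model.positions - center) @ rot.T + center + t
        if not np.all(cond.contains(new_pos, margin=0.5)):
            raise ValueError("rigid perturbation moved voxels outside the conductor")

    return replace(model, positions=new_pos)


# ---------------------------------------------------------------------------
# projection to sensors
# ---------------------------------------------------------------------------

def project_to_sensors(
    model: SourceModel,
    sensors: SensorArray,
    conductor: Conductor | None = None,
    snr: float = np.inf,
    n_epochs: int = 1,
    seed: int = 0,
    condition_tag: str = "native",
) -> EpochSet:
    """Forward-project source series and add white sensor noise.

    ``B(t) = sum_v L_v s_v(t) + noise``; the noise standard deviation is set
    so that sensor-level signal power / noise power equals ``snr``. The total
    source sample count must divide evenly into ``n_epochs`` epochs.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    cond = conductor or model.conductor
    if model.n_samples % n_epochs:
        raise ValueError("n_samples must be divisible by n_epochs")

    lf = np.stack(
        [
            compute_leadfield(model.positions[v], model.orientations[v], sensors, cond).entries
            for v in range(model.n_voxels)
        ],
        axis=1,
    )  # (M, V)
    b = lf @ model.series  # (M, n_samples)

    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        p_signal = np.mean(b ** 2)
        if p_signal == 0:
            raise ValueError("silent source model: cannot set SNR")
        sigma = np.sqrt(p_signal / snr)
        b = b + sigma * rng.standard_normal(b.shape)

    epoch_len = model.n_samples // n_epochs
    data = b.reshape(sensors.n_channels, n_epochs, epoch_len).transpose(0, 2, 1)
    es = EpochSet(data=data, fs=model.fs, condition_tag=condition_tag)
    es.validate_bands(model.band_defs)
    return es
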