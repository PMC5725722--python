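"""LCMV/SAM scalar beamformer, pseudo-Z, and ROI representative voxels.

The virtual electrode (VE) at a source voxel is the unit-gain linearly
constrained minimum-variance projection of the sensor data,

    VE = (L^T C^-1 L)^-1 L^T C^-1 B = W^T B,

with lead field L (scalar, after orientation selection) and regularized data
covariance C. The dipole orientation per voxel is the power-maximizing (SAM)
orientation: the eigenvector of the smallest non-null eigenvalue of
L_vec^T C^-1 L_vec. Each ROI is summarized by a single representative voxel,
either the pseudo-Z peak per band or the band-independent geometric centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh

from .bands import BandDefinition, TOTAL_RANGE
from .spectral import bandpass_fft
from .synthetic import Conductor, EpochSet, LeadFieldMatrix, SensorArray, SourceModel, compute_leadfield

__all__ = [
    "SensorCovariance",
    "BeamformerWeights",
    "VirtualElectrodeSet",
    "estimate_covariance",
    "lcmv_weights",
    "scalar_orientation",
    "pseudo_z",
    "select_representative",
    "voxel_distance",
    "atlas_beamform",
]


@dataclass
class SensorCovariance:
    """Regularized pooled sensor covariance C + lam * (tr C / M) * I."""

    matrix: np.ndarray
    n_samples_used: int
    lam: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    def cho(self):
        return cho_factor(self.matrix)


@dataclass
class BeamformerWeights:
    """Unit-gain spatial filter for one voxel and band."""

    w: np.ndarray
    voxel_id: int = -1
    band: str = ""


@dataclass
class VirtualElectrodeSet:
    """Reconstructed ROI time series and representative voxels.

    ``series[band]`` is (R, samples, epochs), band-filtered, at that band's
    representative voxel. ``broadband[band]`` is the broadband VE at the same
    voxel (feeds relative power). ``rep_voxel[band]`` are 0-based indices into
    the anatomy model's voxel arrays, and ``rep_position[band]`` their
    coordinates (mm) in that anatomy's frame.
    """

    series: dict = field(default_factory=dict)
    broadband: dict = field(default_factory=dict)
    rep_voxel: dict = field(default_factory=dict)
    rep_position: dict = field(default_factory=dict)
    method: str = "peak"
    condition_tag: str = "native"


# ---------------------------------------------------------------------------
# covariance and weights
# ---------------------------------------------------------------------------

def estimate_covariance(epochs: EpochSet | np.ndarray, lam: float = 0.01) -> SensorCovariance:
    """Pooled covariance over concatenated epochs, Tikhonov-regularized.

    C is the sample covariance of channel-demeaned data; regularization adds
    ``lam * (trace(C)/M)`` to the diagonal. Raises on non-finite input and on
    all-zero data ("zero covariance").
    """
    x = epochs.concatenated() if isinstance(epochs, EpochSet) else np.asarray(epochs, float)
    if x.ndim != 2:
        raise ValueError("expected channels x samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sensor data")
    m, n = x.shape
    if n < m:
        import warnings

        warnings.warn(
            f"fewer samples ({n}) than channels ({m}); covariance is rank-deficient",
            stacklevel=2,
        )
    xc = x - x.mean(axis=1, keepdims=True)
    c = (xc @ xc.T) / n
    tr = np.trace(c)
    if tr <= 0:
        raise ValueError("zero covariance: sensor data has no variance")
    c = c + lam * (tr / m) * np.eye(m)
    return SensorCovariance(matrix=0.5 * (c + c.T), n_samples_used=n, lam=lam)


def lcmv_weights(L: LeadFieldMatrix | np.ndarray, C: SensorCovariance) -> BeamformerWeights:
    """Unit-gain LCMV weights W = C^-1 L / (L^T C^-1 L)."""
    lvec = L.entries if isinstance(L, LeadFieldMatrix) else np.asarray(L, float)
    if lvec.ndim != 1:
        raise ValueError("scalar-mode lead field required (use scalar_orientation first)")
    if np.linalg.norm(lvec) < 1e-12:
        raise ValueError("silent source: lead field is (numerically) zero")
    cinv_l = cho_solve(C.cho(), lvec)
    denom = float(lvec @ cinv_l)
    if denom <= 0:
        raise ValueError("non-positive projected power; covariance not PD?")
    w = cinv_l / denom
    vid = L.voxel_id if isinstance(L, LeadFieldMatrix) else -1
    return BeamformerWeights(w=w, voxel_id=vid)


def scalar_orientation(L_vec: np.ndarray, C: SensorCovariance,
                       null_tol: float = 1e-8) -> np.ndarray:
    """SAM power-maximizing dipole orientation.

    Eigen-decomposes ``A = L_vec^T C^-1 L_vec`` (3x3); directions with
    eigenvalue below ``null_tol`` times the largest are treated as the null
    (quasi-radial) space and excluded; among the rest the eigenvector of the
    smallest eigenvalue maximizes unit-gain output power 1/(u^T A u). The
    sign is fixed so the first non-zero component is positive.
    """
    L_vec = np.asarray(L_vec, float)
    if L_vec.ndim != 2 or L_vec.shape[1] != 3:
        raise ValueError("L_vec must be channels x 3")
    a = L_vec.T @ cho_solve(C.cho(), L_vec)
    vals, vecs = eigh(0.5 * (a + a.T))
    top = vals[-1]
    if top <= 0:
        raise ValueError("all-zero tangential lead field")
    keep = np.flatnonzero(vals > null_tol * top)
    if keep.size == 0:
        raise ValueError("all-zero tangential lead field")
    u = vecs[:, keep[0]]  # smallest eigenvalue outside the null space
    for comp in u:
        if abs(comp) > 1e-12:
            if comp < 0:
                u = -u
            break
    return u / np.linalg.norm(u)


def pseudo_z(W: BeamformerWeights | np.ndarray, C: SensorCovariance,
             noise_power: float | None = None) -> float:
    """Pseudo-Z: sqrt of beamformer output power over projected noise power.

    ``Z = sqrt((W^T C W) / (sigma2 * W^T W))``. The default noise power
    sigma2 is the mean of the smallest ceil(M/4) eigenvalues of C.
    """
    w = W.w if isinstance(W, BeamformerWeights) else np.asarray(W, float)
    ww = float(w @ w)
    if ww == 0:
        raise ValueError("zero weight vector")
    if noise_power is None:
        noise_power = noise_power_estimate(C)
    if noise_power <= 0:
        raise ValueError("noise power must be > 0")
    return float(np.sqrt((w @ C.matrix @ w) / (noise_power * ww)))


def noise_power_estimate(C: SensorCovariance) -> float:
    """Mean of the smallest ceil(M/4) covariance eigenvalues."""
    vals = np.linalg.eigvalsh(C.matrix)
    m = C.matrix.shape[0]
    k = int(np.ceil(m / 4))
    return float(vals[:k].mean())


# ---------------------------------------------------------------------------
# representative voxels
# ---------------------------------------------------------------------------

def select_representative(
    roi_voxels: Sequence[int],
    positions: np.ndarray,
    method: str,
    pseudo_z_map: Mapping[int, float] | np.ndarray | None = None,
) -> int:
    """Representative voxel of a ROI: pseudo-Z ``peak`` or geometric ``centroid``.

    ``peak`` picks the argmax of the pseudo-Z map over the ROI's voxels;
    ``centroid`` picks the voxel minimizing the summed Euclidean distance to
    all other ROI voxels. Ties break to the lowest voxel id.
    """
    roi_voxels = np.asarray(list(roi_voxels), int)
    if roi_voxels.size == 0:
        raise ValueError("empty ROI")
    if method == "peak":
        if pseudo_z_map is None:
            raise ValueError("peak method requires a pseudo-Z map")
        z = np.array([pseudo_z_map[v] for v in roi_voxels], float)
        order = np.lexsort((roi_voxels, -z))
        return int(roi_voxels[order[0]])
    if method == "centroid":
        pos = np.asarray(positions, float)[roi_voxels]
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1).sum(axis=1)
        order = np.lexsort((roi_voxels, d))
        return int(roi_voxels[order[0]])
    raise ValueError(f"unknown method {method!r}")


def voxel_distance(v_native: np.ndarray, v_template: np.ndarray) -> float:
    """Euclidean distance (mm) between two representative-voxel coordinates."""
    a = np.asarray(v_native, float)
    b = np.asarray(v_template, float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("expected 3D coordinates")
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# atlas-level reconstruction
# ---------------------------------------------------------------------------

def _stack_leadfields(anatomy: SourceModel, sensors: SensorArray,
                      conductor: Conductor) -> np.ndarray:
    """Vector lead fields for every voxel: (M, V, 3)."""
    return np.stack(
        [
            compute_leadfield(anatomy.positions[v], None, sensors, conductor).entries
            for v in range(anatomy.n_voxels)
        ],
        axis=1,
    )


def atlas_beamform(
    epochs: EpochSet,
    anatomy: SourceModel,
    sensors: SensorArray,
    bands: Sequence[BandDefinition],
    method: str = "peak",
    lam: float = 0.01,
    total_range: tuple[float, float] = TOTAL_RANGE,
    condition_tag: str | None = None,
) -> VirtualElectrodeSet:
    """Reconstruct one VE per ROI per band under a given anatomy.

    Per band: the epochs are band-filtered, a pooled band covariance is
    estimated, SAM orientations and unit-gain weights are computed for every
    voxel, and the representative voxel per ROI is selected (pseudo-Z peak,
    or centroid from geometry alone). ``series`` holds the band-filtered VE
    at the representative voxel; ``broadband`` the VE of the same voxel under
    broadband (``total_range``) weights, used for relative power.

    The anatomy argument carries the voxel geometry of the condition under
    which reconstruction is performed (native or displaced template); the
    sensor data are condition-independent.
    """
    if sensors.n_channels != epochs.n_channels:
        raise ValueError("sensor array / epoch channel count mismatch")
    m, s, e = epochs.data.shape
    conductor = anatomy.conductor
    lf_vec = _stack_leadfields(anatomy, sensors, conductor)  # (M, V, 3)
    n_voxels = anatomy.n_voxels
    rois = np.arange(1, anatomy.n_rois + 1)

    ves = VirtualElectrodeSet(
        method=method,
        condition_tag=condition_tag or epochs.condition_tag,
    )

    # broadband pass (feeds relative power)
    bb_band = BandDefinition("broadband", total_range[0], total_range[1])
    x_bb = bandpass_fft(epochs.data, bb_band, epochs.fs, axis=1)
    cov_bb = estimate_covariance(
        x_bb.transpose(0, 2, 1).reshape(m, -1), lam=lam
    )
    cho_bb = cov_bb.cho()

    def unit_gain_weights(cov: SensorCovariance, cho, scalar_lf: np.ndarray) -> np.ndarray:
        cinv_l = cho_solve(cho, scalar_lf)          # (M, V)
        denom = np.einsum("mv,mv->v", scalar_lf, cinv_l)
        if np.any(denom <= 0):
            raise ValueError("non-positive projected power")
        return cinv_l / denom                       # (M, V)

    for band in bands:
        x_band = bandpass_fft(epochs.data, band, epochs.fs, axis=1)
        cov = estimate_covariance(x_band.transpose(0, 2, 1).reshape(m, -1), lam=lam)
        cho = cov.cho()

        orient = np.stack(
            [scalar_orientation(lf_vec[:, v, :], cov) for v in range(n_voxels)]
        )  # (V, 3)
        scalar_lf = np.einsum("mvk,vk->mv", lf_vec, orient)  # (M, V)
        weights = unit_gain_weights(cov, cho, scalar_lf)

        if method == "peak":
            sigma2 = noise_power_estimate(cov)
            wcw = np.einsum("mv,mn,nv->v", weights, cov.matrix, weights)
            ww = np.einsum("mv,mv->v", weights, weights)
            zmap = np.sqrt(wcw / (sigma2 * ww))
            rep = np.array(
                [
                    select_representative(anatomy.roi_voxels(r), anatomy.positions,
                                          "peak", zmap)
                    for r in rois
                ]
            )
        elif method == "centroid":
            rep = np.array(
                [
                    select_representative(anatomy.roi_voxels(r), anatomy.positions,
                                          "centroid")
                    for r in rois
                ]
            )
        else:
            raise ValueError(f"unknown method {method!r}")

        w_rep = weights[:, rep]                              # (M, R)
        series = np.einsum("mr,mse->rse", w_rep, x_band)     # (R, S, E)

        # broadband VE at the same representative voxels
        lf_bb = np.einsum("mvk,vk->mv", lf_vec[:, rep, :],
                          np.stack([scalar_orientation(lf_vec[:, v, :], cov_bb)
                                    for v in rep]))
        w_bb = unit_gain_weights(cov_bb, cho_bb, lf_bb)
        series_bb = np.einsum("mr,mse->rse", w_bb, x_bb)

        ves.series[band.name] = series
        ves.broadband[band.name] = series_bb
        ves.rep_voxel[band.name] = rep
        ves.rep_position[band.name] = anatomy.positions[rep]

    return ves
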