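"""Scalar (SAM-type) beamformer virtual sensors.

For each source location with leadfield columns L (n_channels x 3), the
orientation theta maximizing the output power-to-noise ratio

    Z(theta) = (theta' L' C^-1 L theta)^-1 / (theta' L' C^-1 N C^-1 L theta)
               * (theta' L' C^-1 L theta)^-2 ... = pseudo-Z of w(theta)

reduces to the largest eigenvector of the 3x3 generalized eigenproblem
A theta = lambda B theta with A = L' C^-1 L and B = L' C^-1 N C^-1 L. The
weights follow the minimum-variance closed form

    w = C^-1 l(theta) / (l(theta)' C^-1 l(theta))          (unit gain)

and are then noise-normalized by sqrt(w' N w) (unit-noise-gain), so that pure
noise-covariance-distributed input yields unit output variance. C is the data
covariance of the 80 Hz high-passed recording; N is the noise covariance of
the first 10 s of the unfiltered recording. C is diagonally loaded by
lambda * mean(diag(C)) before inversion (default lambda = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg

from .filters import FilterSpec, apply_zero_phase_array
from .recording import MultichannelRecording
from .synthetic import SyntheticLeadfield

__all__ = [
    "CovarianceEstimate",
    "BeamformerWeights",
    "compute_covariance",
    "scalar_weights",
    "compute_weights",
    "reconstruct_virtual_sensors",
]


@dataclass
class CovarianceEstimate:
    """Sample covariance with provenance (window, filter, loading)."""

    matrix: np.ndarray
    n_samples: int
    window_s: tuple[float, float]
    filter_kind: Optional[str] = None
    loading: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(self.matrix)
        if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
            raise ValueError("covariance must be positive semi-definite")

    def loaded(self, loading: float) -> np.ndarray:
        """Diagonally loaded matrix: C + loading * mean(diag(C)) * I."""
        if loading < 0:
            raise ValueError("loading must be >= 0")
        mu = float(np.mean(np.diag(self.matrix)))
        return self.matrix + loading * mu * np.eye(self.matrix.shape[0])


@dataclass
class BeamformerWeights:
    """Noise-normalized scalar weights, one row per source."""

    weights: np.ndarray  # (n_sources, n_channels)
    orientations: np.ndarray  # (n_sources, 3), unit vectors
    normalization: str = "unit-noise-gain"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-D (n_sources, n_channels)")
        if self.orientations.shape != (self.weights.shape[0], 3):
            raise ValueError("need one unit orientation per source")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors")

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0]


def compute_covariance(
    recording: MultichannelRecording,
    window_s: Optional[tuple[float, float]] = None,
    filter_spec: Optional[FilterSpec] = None,
) -> CovarianceEstimate:
    """Sample covariance of a (optionally filtered) window of the recording.

    The channel means over the window are removed. If the window holds fewer
    samples than channels the estimate is rank deficient; a warning is issued
    and downstream loading is mandatory.
    """
    fs = recording.fs
    if window_s is None:
        window_s = (0.0, recording.duration_s)
    start = int(round(window_s[0] * fs))
    end = int(round(window_s[1] * fs))
    if not (0 <= start < end <= recording.n_samples):
        raise ValueError(f"window {window_s} outside the record")
    data = recording.data[start:end]
    if filter_spec is not None:
        data = apply_zero_phase_array(filter_spec, data)
    n = data.shape[0]
    if n < recording.n_channels:
        import warnings

        warnings.warn(
            "covariance window shorter than n_channels: estimate is rank "
            "deficient, diagonal loading is mandatory",
            stacklevel=2,
        )
    centered = data - data.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / max(n - 1, 1)
    cov = 0.5 * (cov + cov.T)
    return CovarianceEstimate(
        matrix=cov,
        n_samples=n,
        window_s=(start / fs, end / fs),
        filter_kind=None if filter_spec is None else filter_spec.kind,
    )


def scalar_weights(
    leadfield: np.ndarray,
    data_cov: CovarianceEstimate,
    noise_cov: CovarianceEstimate,
    loading: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form scalar beamformer weights for one source.

    Parameters
    ----------
    leadfield
        (n_channels, 3) gain matrix for the source.
    data_cov, noise_cov
        Data covariance (80 Hz high-passed signal) and noise covariance
        (first seconds of the unfiltered signal).
    loading
        Diagonal-loading fraction applied to the data covariance.

    Returns
    -------
    (weights_row, orientation): the unit-noise-gain-normalized weight vector
    (n_channels,) and the optimal unit orientation (3,).
    """
    L = np.asarray(leadfield, dtype=float)
    if L.ndim != 2 or L.shape[1] != 3:
        raise ValueError("leadfield must have shape (n_channels, 3)")
    if np.linalg.matrix_rank(L) < 2:
        raise ValueError("degenerate leadfield: rank < 2")
    C = data_cov.loaded(loading)
    N = noise_cov.matrix
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "data covariance singular even after loading"
        ) from exc
    A = L.T @ Cinv @ L  # power-related quadratic form
    B = L.T @ Cinv @ N @ Cinv @ L  # projected-noise quadratic form
    A = 0.5 * (A + A.T)
    B = 0.5 * (B + B.T)
    # orientation maximizing pseudo-Z: largest generalized eigenvector
    eigvals, eigvecs = linalg.eigh(A, B)
    theta = eigvecs[:, -1]
    theta = theta / np.linalg.norm(theta)
    # deterministic sign: largest-magnitude component positive
    if theta[np.argmax(np.abs(theta))] < 0:
        theta = -theta
    l = L @ theta
    denom = float(l @ Cinv @ l)
    if denom <= 0:
        raise np.linalg.LinAlgError("non-positive projected power; bad covariance")
    w = Cinv @ l / denom  # unit gain: w' l = 1
    w = w / np.sqrt(float(w @ N @ w))  # unit noise gain
    return w, theta


def compute_weights(
    leadfields: SyntheticLeadfield,
    data_cov: CovarianceEstimate,
    noise_cov: CovarianceEstimate,
    loading: float = 0.05,
) -> BeamformerWeights:
    """Scalar weights for every source in a leadfield set."""
    rows = np.empty((leadfields.n_sources, leadfields.n_channels))
    thetas = np.empty((leadfields.n_sources, 3))
    for s in range(leadfields.n_sources):
        rows[s], thetas[s] = scalar_weights(
            leadfields.gain[:, s, :], data_cov, noise_cov, loading
        )
    return BeamformerWeights(weights=rows, orientations=thetas)


def reconstruct_virtual_sensors(
    recording: MultichannelRecording, weights: BeamformerWeights
) -> MultichannelRecording:
    """Virtual-sensor time series: sensor data projected through the weights."""
    if weights.weights.shape[1] != recording.n_channels:
        raise ValueError(
            f"weights expect {weights.weights.shape[1]} channels, "
            f"recording has {recording.n_channels}"
        )
    virtual = recording.data @ weights.weights.T
    labels = [f"vs{i}" for i in range(weights.n_sources)]
    return MultichannelRecording(data=virtual, fs=recording.fs, channel_labels=labels)
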