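"""Core data containers for the rotational-dynamics pipeline.

The pipeline moves through four representations:

``TrialSet``
    Raw trial-structured binned spike counts per electrode, each trial
    labelled with a movement condition (e.g. one of 8 center-out target
    directions) and carrying event markers.
``ConditionAveragedRates``
    Trial-averaged, optionally smoothed firing rates (spikes/s), shaped
    conditions x electrodes x time.
``StateMatrix``
    The dimensionality-reduced population state ``X_red`` (d x C*T,
    organised as C condition blocks of T columns) together with the PCA
    basis and normalisation metadata needed to map back to electrodes.
``DerivativePair``
    States and their per-bin differences, aligned column-by-column, used
    to fit linear dynamics.

All containers are plain dataclasses with validation on construction and
HDF5 round-trip support where they cross process boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import h5py

__all__ = [
    "TrialSet",
    "ConditionAveragedRates",
    "StateMatrix",
    "DerivativePair",
    "DynamicsFit",
    "JPCAPlane",
]


@dataclass
class TrialSet:
    """Trial-structured binned spike counts.

    Parameters
    ----------
    counts : ndarray, shape (n_trials, n_electrodes, n_bins)
        Non-negative integer spike counts per bin.
    condition : ndarray, shape (n_trials,)
        Condition index per trial, in ``[0, n_conditions)``.
    bin_width_ms : float
        Width of each time bin in milliseconds; shared by all trials.
    epoch_markers : ndarray, shape (n_trials, 2)
        Per-trial ``(target_onset_ms, epoch_start_ms)`` relative to the
        start of the trial's first bin.
    electrode_ids : sequence of str, optional
        Channel labels; defaults to ``e000, e001, ...``.
    seed : int, optional
        Generator seed when the set is synthetic.
    """

    counts: np.ndarray
    condition: np.ndarray
    bin_width_ms: float
    epoch_markers: np.ndarray
    electrode_ids: Sequence[str] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.condition = np.asarray(self.condition, dtype=np.int64)
        self.epoch_markers = np.asarray(self.epoch_markers, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (n_trials, n_electrodes, n_bins)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.condition.shape != (self.counts.shape[0],):
            raise ValueError("condition must have one entry per trial")
        if np.any(self.condition < 0):
            raise ValueError("condition indices must be non-negative")
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be positive")
        if self.epoch_markers.shape != (self.counts.shape[0], 2):
            raise ValueError("epoch_markers must be (n_trials, 2)")
        if self.electrode_ids is None:
            self.electrode_ids = [f"e{i:03d}" for i in range(self.n_electrodes)]
        elif len(self.electrode_ids) != self.n_electrodes:
            raise ValueError("electrode_ids length must equal n_electrodes")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def n_conditions(self) -> int:
        return int(self.condition.max()) + 1 if self.n_trials else 0

    def to_hdf5(self, path) -> None:
        """Write to an HDF5 container (datasets /counts, /condition,
        /epoch_markers; attributes bin_width_ms, seed, electrode_ids)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts, compression="gzip")
            f.create_dataset("condition", data=self.condition)
            f.create_dataset("epoch_markers", data=self.epoch_markers)
            f.attrs["bin_width_ms"] = self.bin_width_ms
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            f.attrs["electrode_ids"] = [str(e) for e in self.electrode_ids]

    @classmethod
    def from_hdf5(cls, path) -> "TrialSet":
        with h5py.File(path, "r") as f:
            seed = f.attrs.get("seed")
            ids = f.attrs.get("electrode_ids")
            return cls(
                counts=f["counts"][...],
                condition=f["condition"][...],
                bin_width_ms=float(f.attrs["bin_width_ms"]),
                epoch_markers=f["epoch_markers"][...],
                electrode_ids=None if ids is None else [str(s) for s in ids],
                seed=None if seed is None else int(seed),
            )


@dataclass
class ConditionAveragedRates:
    """Trial-averaged firing rates, conditions x electrodes x time (spikes/s)."""

    rates: np.ndarray
    bin_width_ms: float
    time_axis_ms: np.ndarray
    condition_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.time_axis_ms = np.asarray(self.time_axis_ms, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (C, E, T)")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if self.time_axis_ms.shape != (self.rates.shape[2],):
            raise ValueError("time_axis_ms must match the time dimension")
        if self.condition_labels is None:
            self.condition_labels = np.arange(self.rates.shape[0])
        else:
            self.condition_labels = np.asarray(self.condition_labels)

    @property
    def n_conditions(self) -> int:
        return self.rates.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.rates.shape[1]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    def copy_with(self, rates: np.ndarray, time_axis_ms: np.ndarray | None = None) -> "ConditionAveragedRates":
        return ConditionAveragedRates(
            rates=rates,
            bin_width_ms=self.bin_width_ms,
            time_axis_ms=self.time_axis_ms if time_axis_ms is None else time_axis_ms,
            condition_labels=self.condition_labels,
        )


@dataclass
class StateMatrix:
    """Reduced population state ``X_red`` plus the projection metadata.

    ``X_red`` has shape (d, C*T) with columns organised as C condition
    blocks of T time points each.  ``pca_basis`` (E x d, orthonormal
    columns) and ``pca_mean`` (E,) map electrode-space samples into the
    reduced space; ``total_variance`` is the total sum of squares of the
    centered electrode-space samples, used to express plane variance as
    a fraction of the high-dimensional data variance.
    """

    X_red: np.ndarray
    pca_basis: np.ndarray
    per_dim_variance: np.ndarray
    n_conditions: int
    n_timebins: int
    bin_width_ms: float
    d: int = 6
    epoch_window_ms: tuple[float, float] = (0.0, 0.0)
    pca_mean: np.ndarray | None = None
    total_variance: float | None = None
    normalization_record: dict | None = None

    def __post_init__(self) -> None:
        self.X_red = np.asarray(self.X_red, dtype=float)
        self.pca_basis = np.asarray(self.pca_basis, dtype=float)
        self.per_dim_variance = np.asarray(self.per_dim_variance, dtype=float)
        d, n = self.X_red.shape
        if d != self.d:
            raise ValueError(f"X_red has {d} rows but d={self.d}")
        if n != self.n_conditions * self.n_timebins:
            raise ValueError("X_red columns must equal n_conditions * n_timebins")
        g = self.pca_basis.T @ self.pca_basis
        if not np.allclose(g, np.eye(d), atol=1e-10):
            raise ValueError("pca_basis columns must be orthonormal")
        if np.any(np.diff(self.per_dim_variance[: self.d]) > 1e-12):
            raise ValueError("per_dim_variance must be non-increasing")
        if self.total_variance is None:
            self.total_variance = float(np.sum(self.X_red**2))

    def condition_block(self, c: int) -> np.ndarray:
        """View of condition ``c``'s trajectory, shape (d, T)."""
        t = self.n_timebins
        return self.X_red[:, c * t : (c + 1) * t]

    def as_trajectories(self) -> np.ndarray:
        """Reshape to (C, d, T)."""
        return np.stack([self.condition_block(c) for c in range(self.n_conditions)])

    @classmethod
    def from_trajectories(cls, traj: np.ndarray, bin_width_ms: float, **kw) -> "StateMatrix":
        """Build directly from latent trajectories (C, d, T) with an
        identity basis — used when dynamics are fitted to known latents."""
        traj = np.asarray(traj, dtype=float)
        c, d, t = traj.shape
        x = np.concatenate([traj[i] for i in range(c)], axis=1)
        ss = np.sum(x**2, axis=1)
        return cls(
            X_red=x,
            pca_basis=np.eye(d),
            per_dim_variance=np.sort(ss / max(ss.sum(), np.finfo(float).tiny))[::-1],
            n_conditions=c,
            n_timebins=t,
            bin_width_ms=bin_width_ms,
            d=d,
            **kw,
        )


@dataclass
class DerivativePair:
    """States X and per-bin state changes X_dot, aligned columns.

    Differences are taken within each condition block only; the final
    time point of each block is dropped from X so shapes match, giving
    d x C*(T-1) matrices.
    """

    X: np.ndarray
    X_dot: np.ndarray
    bin_width_ms: float
    n_conditions: int
    n_timebins: int  # T-1, per condition block

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.X_dot = np.asarray(self.X_dot, dtype=float)
        if self.X.shape != self.X_dot.shape:
            raise ValueError("X and X_dot must share a shape")
        if self.X.shape[1] != self.n_conditions * self.n_timebins:
            raise ValueError("column count inconsistent with blocks")

    @property
    def d(self) -> int:
        return self.X.shape[0]


@dataclass
class DynamicsFit:
    """Fitted transition matrices for the reduced state.

    ``M`` is the unconstrained least-squares solution of
    ``X_dot = M X``; ``M_skew`` is the best skew-symmetric solution
    (``M_skew = -M_skew.T``), which can only generate rotations.
    R-squared values use the uncentered sum of squares of ``X_dot``.
    """

    M: np.ndarray
    M_skew: np.ndarray
    r2_unconstrained: float
    r2_skew: float
    residual_norm_unconstrained: float
    residual_norm_skew: float

    def __post_init__(self) -> None:
        if not np.allclose(self.M_skew + self.M_skew.T, 0, atol=1e-10):
            raise ValueError("M_skew must be skew-symmetric")

    def to_dict(self) -> dict:
        return {
            "M": self.M.tolist(),
            "M_skew": self.M_skew.tolist(),
            "r2_unconstrained": self.r2_unconstrained,
            "r2_skew": self.r2_skew,
            "residual_norm_unconstrained": self.residual_norm_unconstrained,
            "residual_norm_skew": self.residual_norm_skew,
        }


@dataclass
class JPCAPlane:
    """An oriented two-dimensional rotational plane.

    ``basis`` holds jPC1 and jPC2 as orthonormal columns in the reduced
    space.  ``angular_frequency`` is the plane's rotation rate in rad/s
    obtained from the eigenvalue magnitude divided by the bin width;
    ``angular_frequency_corrected`` additionally undoes the finite-
    difference discretisation (arcsin correction), converging to the
    raw value as the bin width shrinks.
    """

    basis: np.ndarray  # (d, 2), columns jPC1, jPC2
    angular_frequency: float  # rad/s, |eigenvalue| / bin width
    angular_frequency_corrected: float  # rad/s, arcsin-corrected
    variance_captured_reduced: float
    variance_captured_full: float
    orientation_flipped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.shape[1] != 2:
            raise ValueError("basis must have two columns")
        g = self.basis.T @ self.basis
        if not np.allclose(g, np.eye(2), atol=1e-10):
            raise ValueError("plane basis must be orthonormal")
        if self.angular_frequency < 0:
            raise ValueError("angular_frequency must be non-negative")
        for v in (self.variance_captured_reduced, self.variance_captured_full):
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError("variance fractions must lie in [0, 1]")

    @property
    def frequency_hz(self) -> float:
        return self.angular_frequency_corrected / (2 * np.pi)

    def to_dict(self) -> dict:
        return {
            "basis": self.basis.tolist(),
            "angular_frequency": self.angular_frequency,
            "angular_frequency_corrected": self.angular_frequency_corrected,
            "frequency_hz": self.frequency_hz,
            "variance_captured_reduced": self.variance_captured_reduced,
            "variance_captured_full": self.variance_captured_full,
            "orientation_flipped": self.orientation_flipped,
        }
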