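"""Rotational-structure statistics.

Three summaries quantify how rotational the population dynamics are:

* the fraction of state-change variance explained by the skew-symmetric
  (purely rotational) model, ``r2_skew = 1 - |X_dot - M_skew X|^2 /
  |X_dot|^2``, compared against the unconstrained fit;
* the variance each jPCA plane captures, both of the reduced state and
  of the high-dimensional (soft-normalised, mean-centered) data;
* the distribution of the angle q between the in-plane state x and its
  derivative x_dot: pure rotation gives angles near pi/2, pure
  scaling/expansion gives angles near 0 or pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import DerivativePair, StateMatrix, JPCAPlane

__all__ = [
    "RotationalVarianceReport",
    "AngleHistogram",
    "rotational_variance_fraction",
    "angle_distribution",
    "plane_variance_summary",
]


@dataclass
class RotationalVarianceReport:
    """Fractions of state-change variance explained by the rotational
    (skew) and unconstrained linear models."""

    r2_skew: float
    r2_unconstrained: float | None
    d_used: int
    n_columns: int

    def __post_init__(self) -> None:
        if self.r2_unconstrained is not None and self.r2_skew > self.r2_unconstrained + 1e-12:
            raise ValueError("r2_skew cannot exceed r2_unconstrained")


def rotational_variance_fraction(
    pair: DerivativePair,
    M_skew: np.ndarray,
    M: np.ndarray | None = None,
    centered: bool = False,
) -> RotationalVarianceReport:
    """R-squared of the skew model on the state changes.

    The denominator is the uncentered sum of squares ``|X_dot|_F^2``
    (the variance of the changes in neural state about zero); set
    ``centered=True`` to subtract the column mean of ``X_dot`` first.
    """
    xd = pair.X_dot
    if centered:
        xd = xd - xd.mean(axis=1, keepdims=True)
    ss = float(np.sum(xd**2))
    if ss == 0:
        raise ValueError("X_dot is identically zero; variance fraction undefined")
    r2s = 1.0 - float(np.sum((pair.X_dot - M_skew @ pair.X) ** 2)) / ss
    r2u = None
    if M is not None:
        r2u = 1.0 - float(np.sum((pair.X_dot - M @ pair.X) ** 2)) / ss
    return RotationalVarianceReport(
        r2_skew=r2s, r2_unconstrained=r2u, d_used=pair.d, n_columns=pair.X.shape[1]
    )


@dataclass
class AngleHistogram:
    """Histogram over [0, pi] of the state/derivative angle."""

    bin_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    n_samples: int
    n_skipped: int = 0
    source: str = "data"

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        widths = np.diff(self.bin_edges)
        if self.n_samples > 0 and abs(float(self.density @ widths) - 1.0) > 1e-9:
            raise ValueError("density must integrate to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode(self) -> float:
        """Center of the highest-density bin."""
        return float(self.bin_centers[int(np.argmax(self.density))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
                "density": self.density,
            }
        )


def angles_between_state_and_derivative(proj: np.ndarray) -> np.ndarray:
    """Angles q = arccos(x . dx / (|x| |dx|)) for 2-D trajectories
    (C, 2, T), pooled over conditions; zero-norm pairs are dropped."""
    proj = np.asarray(proj, dtype=float)
    if proj.ndim != 3 or proj.shape[1] != 2:
        raise ValueError("expected (C, 2, T) projected trajectories")
    x = proj[:, :, :-1]
    dx = np.diff(proj, axis=2)
    nx = np.linalg.norm(x, axis=1)
    nd = np.linalg.norm(dx, axis=1)
    ok = (nx > 0) & (nd > 0)
    dot = np.sum(x * dx, axis=1)
    q = np.arccos(np.clip(dot[ok] / (nx[ok] * nd[ok]), -1.0, 1.0))
    return q, int(np.sum(~ok))


def angle_distribution(proj: np.ndarray, n_bins: int = 36, source: str = "data") -> AngleHistogram:
    """Histogram of state/derivative angles for in-plane trajectories.

    Angles are pooled over all conditions and time steps without
    magnitude weighting; bins partition [0, pi].
    """
    q, n_skipped = angles_between_state_and_derivative(proj)
    if q.size == 0:
        raise ValueError("no valid (state, derivative) pairs")
    edges = np.linspace(0.0, np.pi, n_bins + 1)
    counts, _ = np.histogram(q, bins=edges)
    density = counts / (counts.sum() * np.diff(edges))
    return AngleHistogram(
        bin_edges=edges,
        counts=counts,
        density=density,
        n_samples=int(q.size),
        n_skipped=n_skipped,
        source=source,
    )


def plane_variance_summary(planes: list[JPCAPlane], state: StateMatrix) -> pd.DataFrame:
    """Per-plane variance fractions in the reduced and full spaces.

    For a full set of d/2 planes the reduced-space fractions sum to 1:
    the planes partition the reduced space orthogonally.
    """
    for p in planes:
        if p.basis.shape[0] != state.d:
            raise ValueError("plane does not match the state's reduced dimension")
    rows = []
    for i, p in enumerate(planes):
        rows.append(
            {
                "plane": i + 1,
                "frequency_hz": p.frequency_hz,
                "angular_frequency_rad_s": p.angular_frequency,
                "variance_captured_reduced": p.variance_captured_reduced,
                "variance_captured_full": p.variance_captured_full,
            }
        )
    return pd.DataFrame(rows)
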