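"""jPCA: skew-symmetric dynamics fitting and rotational plane extraction.

The method compares the reduced neural state ``X`` with its per-bin
change ``X_dot`` and fits two linear dynamical systems,

    X_dot = M X        (M unconstrained, ordinary least squares)
    X_dot = M_skew X   (M_skew constrained skew-symmetric)

A skew-symmetric transition matrix has purely imaginary eigenvalues and
therefore generates pure rotations: the fraction of state-change
variance it explains measures how rotational the population dynamics
are.  The eigenvectors of ``M_skew`` belonging to the largest-magnitude
eigenvalue pairs span the jPCA planes; within each plane the basis is
oriented so the pre-movement initial states spread maximally along
jPC1 and the net rotation is counterclockwise.

``JPCA`` is the model object (statsmodels-style): construct it from a
``StateMatrix`` (or straight from a ``TrialSet`` via
``JPCA.from_trialset``), call :meth:`JPCA.fit`, and work with the
returned :class:`JPCAResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import StateMatrix, DerivativePair, DynamicsFit, JPCAPlane
from .preprocess import preprocess, PreprocessResult

__all__ = [
    "make_derivative_pair",
    "fit_unconstrained",
    "fit_skew",
    "skew_basis",
    "extract_planes",
    "orient_plane",
    "project",
    "JPCA",
    "JPCAResults",
]


def make_derivative_pair(state: StateMatrix) -> DerivativePair:
    """Per-bin differences within each condition block.

    ``X_dot[:, k] = X[:, k+1] - X[:, k]`` inside a block; the final
    time point of each block is dropped from ``X`` so both matrices are
    d x C*(T-1).  Differencing never crosses a condition boundary.
    """
    t = state.n_timebins
    if t < 2:
        raise ValueError("need at least 2 time points per condition")
    blocks_x, blocks_dx = [], []
    for c in range(state.n_conditions):
        b = state.condition_block(c)
        blocks_x.append(b[:, :-1])
        blocks_dx.append(np.diff(b, axis=1))
    return DerivativePair(
        X=np.concatenate(blocks_x, axis=1),
        X_dot=np.concatenate(blocks_dx, axis=1),
        bin_width_ms=state.bin_width_ms,
        n_conditions=state.n_conditions,
        n_timebins=t - 1,
    )


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[0]:
        warnings.warn("states do not span the reduced space; least-norm solution")


def fit_unconstrained(pair: DerivativePair) -> np.ndarray:
    """Least-squares transition matrix: minimises ||X_dot - M X||_F."""
    _check_rank(pair.X)
    # lstsq solves A p = b with A = X.T, p = M.T
    m_t, *_ = np.linalg.lstsq(pair.X.T, pair.X_dot.T, rcond=None)
    return m_t.T


def skew_basis(d: int) -> list[tuple[int, int]]:
    """Index pairs (i, j), i < j, parametrising skew-symmetric d x d
    matrices: parameter k contributes +k at (j, i) and -k at (i, j)."""
    return [(i, j) for i in range(d) for j in range(i + 1, d)]


def fit_skew(pair: DerivativePair) -> np.ndarray:
    """Best skew-symmetric transition matrix.

    Minimises ``||X_dot - M X||_F`` over skew-symmetric ``M`` by exact
    linear least squares in the d(d-1)/2-dimensional skew basis; skew
    symmetry holds by construction.  For d = 2 this reduces to the
    closed form ``k = sum(x1*dx2 - x2*dx1) / sum(|x|^2)``.
    """
    _check_rank(pair.X)
    d, n = pair.X.shape
    idx = skew_basis(d)
    design = np.empty((d * n, len(idx)))
    for col, (i, j) in enumerate(idx):
        b = np.zeros((d, d))
        b[j, i] = 1.0
        b[i, j] = -1.0
        design[:, col] = (b @ pair.X).ravel()
    coef, *_ = np.linalg.lstsq(design, pair.X_dot.ravel(), rcond=None)
    m = np.zeros((d, d))
    for k, (i, j) in enumerate(idx):
        m[j, i] = coef[k]
        m[i, j] = -coef[k]
    return m


def _plane_variances(basis: np.ndarray, state: StateMatrix) -> tuple[float, float]:
    proj = basis.T @ state.X_red
    ss = float(np.sum(proj**2))
    reduced = ss / max(float(np.sum(state.X_red**2)), np.finfo(float).tiny)
    full = ss / max(float(state.total_variance), np.finfo(float).tiny)
    return reduced, full


def _sign_canonical(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip so the first component larger than tol is positive."""
    for x in v:
        if abs(x) > tol:
            return v if x > 0 else -v
    return v


def extract_planes(
    M_skew: np.ndarray,
    state: StateMatrix,
    pre_movement_states: np.ndarray | None = None,
) -> list[JPCAPlane]:
    """Ordered jPCA planes from the eigenstructure of ``M_skew``.

    Eigenvalues of a skew-symmetric matrix come in pairs +/- i*w; each
    pair's eigenvector ``u = a + i b`` yields a real plane spanned by
    the orthonormalised ``{a, b}``.  Planes are ordered by |w|
    descending (ties broken by the deterministic eigendecomposition
    order with a lexicographic sign convention) and then oriented with
    :func:`orient_plane` when pre-movement states are supplied.
    """
    if not np.allclose(M_skew + M_skew.T, 0, atol=1e-8):
        raise ValueError("M_skew must be skew-symmetric")
    d = M_skew.shape[0]
    n_planes = d // 2
    w, v = np.linalg.eig(M_skew)
    pos = np.where(w.imag > 1e-12)[0]
    # sort by |imag| descending; ties keep eig's deterministic order
    pos = pos[np.argsort(-w.imag[pos], kind="stable")]

    dt_s = state.bin_width_ms / 1000.0
    planes: list[JPCAPlane] = []
    used = np.zeros((d, 0))
    for i in pos[:n_planes]:
        a, b = v[:, i].real.copy(), v[:, i].imag.copy()
        # project out previously used directions (guards repeated |w|)
        if used.shape[1]:
            a -= used @ (used.T @ a)
            b -= used @ (used.T @ b)
        q, _ = np.linalg.qr(np.column_stack([a, b]))
        basis = np.column_stack([_sign_canonical(q[:, 0]), _sign_canonical(q[:, 1])])
        used = np.column_stack([used, basis])
        omega_bin = float(w.imag[i])  # rad per bin
        red, full = _plane_variances(basis, state)
        planes.append(
            JPCAPlane(
                basis=basis,
                angular_frequency=omega_bin / dt_s,
                angular_frequency_corrected=float(np.arcsin(min(omega_bin, 1.0)) / dt_s),
                variance_captured_reduced=red,
                variance_captured_full=full,
            )
        )

    if len(planes) < n_planes:
        warnings.warn("zero-frequency eigenvalues: filling planes from the null space")
        # deterministic orthonormal completion of the used basis
        q, _ = np.linalg.qr(np.column_stack([used, np.eye(d)])) if used.shape[1] else (np.eye(d), None)
        comp = q[:, used.shape[1] :]
        k = 0
        while len(planes) < n_planes:
            basis = np.column_stack(
                [_sign_canonical(comp[:, k]), _sign_canonical(comp[:, k + 1])]
            )
            red, full = _plane_variances(basis, state)
            planes.append(
                JPCAPlane(
                    basis=basis,
                    angular_frequency=0.0,
                    angular_frequency_corrected=0.0,
                    variance_captured_reduced=red,
                    variance_captured_full=full,
                )
            )
            k += 2

    if pre_movement_states is not None:
        planes = [orient_plane(p, pre_movement_states, state) for p in planes]
    return planes


def orient_plane(
    plane: JPCAPlane, pre_movement_states: np.ndarray, state: StateMatrix
) -> JPCAPlane:
    """Fix the within-plane basis by the two conventions of the method.

    First rotate the basis so the projected pre-movement (initial)
    states have maximal variance along jPC1 — in closed form, jPC1 is
    the leading eigenvector of the 2x2 covariance of the projected
    initial states.  Then flip jPC2's sign if the summed cross product
    ``sum(x1*dx2 - x2*dx1)`` over the projected trajectories is
    negative, so the net rotation is counterclockwise.
    """
    pre = np.asarray(pre_movement_states, dtype=float)
    if pre.ndim != 2 or pre.shape[0] < 2:
        raise ValueError("need >= 2 condition initial states")
    p = pre @ plane.basis  # (C, 2)
    cov = np.cov(p.T) if p.shape[0] > 1 else np.eye(2)
    flips = dict(plane.orientation_flipped)
    evals, evecs = np.linalg.eigh(cov)
    if abs(evals[1] - evals[0]) <= 1e-12 * max(abs(evals[1]), 1.0):
        basis = plane.basis.copy()  # isotropic spread: keep incoming basis
        flips["spread_tie"] = True
    else:
        lead = evecs[:, 1]  # eigenvector of the larger eigenvalue
        jpc1 = plane.basis @ lead
        jpc2 = plane.basis @ np.array([-lead[1], lead[0]])  # 90 deg ccw in-plane
        basis = np.column_stack([_sign_canonical(jpc1), jpc2])
        # keep jpc2 a +90 deg rotation of jpc1 after any jpc1 sign flip
        if not np.allclose(basis[:, 0], jpc1):
            basis[:, 1] = -basis[:, 1]
        flips["spread_tie"] = False

    traj = state.as_trajectories()  # (C, d, T)
    cross = 0.0
    for c in range(traj.shape[0]):
        xy = basis.T @ traj[c]  # (2, T)
        dxy = np.diff(xy, axis=1)
        cross += float(np.sum(xy[0, :-1] * dxy[1] - xy[1, :-1] * dxy[0]))
    if cross < 0:
        basis = np.column_stack([basis[:, 0], -basis[:, 1]])
        flips["jpc2_sign"] = True
    else:
        flips["jpc2_sign"] = False

    return JPCAPlane(
        basis=basis,
        angular_frequency=plane.angular_frequency,
        angular_frequency_corrected=plane.angular_frequency_corrected,
        variance_captured_reduced=plane.variance_captured_reduced,
        variance_captured_full=plane.variance_captured_full,
        orientation_flipped=flips,
    )


def project(state_or_array, plane: JPCAPlane) -> np.ndarray:
    """Project onto the plane basis.

    Accepts a ``StateMatrix`` (returns (C, 2, T) per-condition
    trajectories) or a plain d x n array (returns 2 x n).
    """
    if isinstance(state_or_array, StateMatrix):
        traj = state_or_array.as_trajectories()
        return np.einsum("dk,cdt->ckt", plane.basis, traj)
    arr = np.asarray(state_or_array, dtype=float)
    if arr.shape[0] != plane.basis.shape[0]:
        raise ValueError("dimension mismatch with plane basis")
    return plane.basis.T @ arr


class JPCA:
    """Rotational-dynamics model of a reduced neural state.

    Parameters
    ----------
    state : StateMatrix
        The reduced population state (d x C*T in condition blocks).
    pre_movement_states : ndarray (C, d), optional
        Initial states used to orient the planes; defaults to the first
        column of each condition block.

    Examples
    --------
    >>> res = JPCA.from_trialset(trials, epoch_start_ms=300).fit()
    >>> res.r2_skew, res.planes[0].variance_captured_full
    """

    def __init__(self, state: StateMatrix, pre_movement_states: np.ndarray | None = None):
        self.state = state
        if pre_movement_states is None:
            pre_movement_states = np.stack(
                [state.condition_block(c)[:, 0] for c in range(state.n_conditions)]
            )
        self.pre_movement_states = np.asarray(pre_movement_states, dtype=float)
        self.preprocessing: PreprocessResult | None = None

    @classmethod
    def from_trialset(cls, trials, **preprocess_kwargs) -> "JPCA":
        """Run the preprocessing chain and build the model from it."""
        prep = preprocess(trials, **preprocess_kwargs)
        obj = cls(prep.state, prep.pre_movement_states)
        obj.preprocessing = prep
        return obj

    @classmethod
    def from_trajectories(cls, traj: np.ndarray, bin_width_ms: float) -> "JPCA":
        """Fit directly to known (C, d, T) trajectories — mainly for
        validation against ground-truth latent dynamics."""
        return cls(StateMatrix.from_trajectories(traj, bin_width_ms))

    def fit(self) -> "JPCAResults":
        pair = make_derivative_pair(self.state)
        m = fit_unconstrained(pair)
        m_skew = fit_skew(pair)
        ss = float(np.sum(pair.X_dot**2))
        if ss == 0:
            raise ValueError("X_dot is identically zero: no state changes to model")
        res_u = float(np.linalg.norm(pair.X_dot - m @ pair.X))
        res_s = float(np.linalg.norm(pair.X_dot - m_skew @ pair.X))
        fitres = DynamicsFit(
            M=m,
            M_skew=m_skew,
            r2_unconstrained=1.0 - res_u**2 / ss,
            r2_skew=1.0 - res_s**2 / ss,
            residual_norm_unconstrained=res_u,
            residual_norm_skew=res_s,
        )
        planes = extract_planes(m_skew, self.state, self.pre_movement_states)
        return JPCAResults(model=self, pair=pair, dynamics=fitres, planes=planes)


@dataclass
class JPCAResults:
    """Fitted rotational dynamics: transition matrices, R-squared
    diagnostics, and the ordered, oriented jPCA planes."""

    model: JPCA
    pair: DerivativePair
    dynamics: DynamicsFit
    planes: list[JPCAPlane]

    @property
    def r2_skew(self) -> float:
        return self.dynamics.r2_skew

    @property
    def r2_unconstrained(self) -> float:
        return self.dynamics.r2_unconstrained

    @property
    def M(self) -> np.ndarray:
        return self.dynamics.M

    @property
    def M_skew(self) -> np.ndarray:
        return self.dynamics.M_skew

    def project(self, plane_index: int = 0) -> np.ndarray:
        """(C, 2, T) trajectories in the chosen plane."""
        return project(self.model.state, self.planes[plane_index])

    def plane_variance_table(self):
        from .stats import plane_variance_summary

        return plane_variance_summary(self.planes, self.model.state)

    def angle_distribution(self, plane_index: int = 0, n_bins: int = 36):
        from .stats import angle_distribution

        return angle_distribution(self.project(plane_index), n_bins=n_bins)

    def summary(self) -> str:
        """Plain-text summary table in the style of statistical model
        results objects."""
        st = self.model.state
        lines = [
            "jPCA rotational dynamics fit",
            "=" * 64,
            f"reduced dims (d):        {st.d}",
            f"conditions x time bins:  {st.n_conditions} x {st.n_timebins}",
            f"bin width:               {st.bin_width_ms:g} ms",
            f"R2 (unconstrained M):    {self.r2_unconstrained:.4f}",
            f"R2 (skew-symmetric M):   {self.r2_skew:.4f}",
            "-" * 64,
            f"{'plane':>5} {'freq (Hz)':>10} {'var. reduced':>13} {'var. full':>10}",
        ]
        for i, p in enumerate(self.planes):
            lines.append(
                f"{i + 1:>5} {p.frequency_hz:>10.3f} "
                f"{p.variance_captured_reduced:>13.3f} {p.variance_captured_full:>10.3f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "dynamics": self.dynamics.to_dict(),
            "planes": [p.to_dict() for p in self.planes],
            "d": self.model.state.d,
            "n_conditions": self.model.state.n_conditions,
            "n_timebins": self.model.state.n_timebins,
            "bin_width_ms": self.model.state.bin_width_ms,
        }
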