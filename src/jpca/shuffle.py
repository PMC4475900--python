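"""Shuffle-control null constructions for rotational structure.

A worry with plane-finding methods is that they may discover rotations
in any sufficiently complex multiphasic data, especially with few
conditions.  The three controls below disrupt the relationship between
pre-movement activity and the movement epoch while preserving each
channel's response complexity; the rotational variance fraction is then
recomputed on the shuffled data through the full analysis chain
(normalisation, PCA, and the skew fit are re-run per shuffle trial).

* ``invert_half`` — per channel, invert the movement-epoch pattern
  around its first bin for a random half of the conditions.
* ``invert_all`` — invert for all conditions (deterministic); this
  merely sign-inverts rotational structure, so much of it survives,
  but any consistent initial-state/phase relationship is destroyed.
* ``reassign`` — reassign each condition's movement epoch onto another
  condition's pre-movement activity with one random permutation shared
  by all channels; the epoch's first-bin rate is appended at the end of
  the pre-movement period to preserve continuity.

All shuffle trials are reproducible from (master seed, trial index) via
counter-based child seeds, so trials are independent of evaluation
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import TrialSet, ConditionAveragedRates
from .preprocess import (
    trial_average,
    smooth_rates,
    extract_epoch,
    soft_normalize,
    mean_center,
    reduce_dims,
)
from .model import make_derivative_pair, fit_skew
from .stats import rotational_variance_fraction

__all__ = [
    "ShuffleResult",
    "shuffle_invert_half",
    "shuffle_invert_all",
    "shuffle_reassign",
    "rotational_r2_for_window",
    "run_shuffle_suite",
    "SHUFFLE_KINDS",
]

SHUFFLE_KINDS = ("invert_half", "invert_all", "reassign")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def shuffle_invert_half(
    rates: ConditionAveragedRates, seed, epoch_start_bin: int = 0
) -> tuple[ConditionAveragedRates, np.ndarray]:
    """Invert the movement-epoch pattern for a random half of the
    conditions, independently per channel.

    The inversion is around the epoch's first bin, ``r'(t) = 2 r(t0) -
    r(t)`` for ``t >= t0``, so continuity with pre-movement activity is
    preserved.  Returns the shuffled rates and the (E, C) boolean mask
    of inverted traces.
    """
    rng = _as_rng(seed)
    c, e, _ = rates.rates.shape
    n_invert = c // 2
    mask = np.zeros((e, c), dtype=bool)
    for ei in range(e):
        mask[ei, rng.choice(c, size=n_invert, replace=False)] = True
    out = rates.rates.copy()
    pivot = out[:, :, epoch_start_bin]  # (C, E)
    sel = mask.T  # (C, E)
    seg = out[:, :, epoch_start_bin:]
    seg[sel] = 2 * pivot[sel][:, None] - seg[sel]
    return rates.copy_with(out), mask


def shuffle_invert_all(
    rates: ConditionAveragedRates, epoch_start_bin: int = 0
) -> ConditionAveragedRates:
    """Invert the movement-epoch pattern around its first bin for every
    channel and condition; deterministic (no randomness involved)."""
    out = rates.rates.copy()
    pivot = out[:, :, epoch_start_bin : epoch_start_bin + 1]
    out[:, :, epoch_start_bin:] = 2 * pivot - out[:, :, epoch_start_bin:]
    return rates.copy_with(out)


def shuffle_reassign(
    rates: ConditionAveragedRates,
    epoch_start_bin: int,
    seed=None,
    perm: np.ndarray | None = None,
) -> tuple[ConditionAveragedRates, np.ndarray, int]:
    """Reassign movement-epoch activity across conditions.

    One permutation of condition indices, shared by all channels, maps
    condition ``c``'s pre-movement activity to condition ``perm[c]``'s
    movement epoch.  The reassigned epoch's first-bin rate is appended
    at the end of the pre-movement period (one inserted bin) so the
    spliced trace is continuous.  Returns (shuffled rates, permutation,
    new epoch start bin).
    """
    if epoch_start_bin < 1:
        raise ValueError("reassign requires a pre-movement segment")
    c, e, t = rates.rates.shape
    if perm is None:
        perm = _as_rng(seed).permutation(c)
    else:
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(c)):
            raise ValueError("perm must be a permutation of the conditions")
    pre = rates.rates[:, :, :epoch_start_bin]
    epoch = rates.rates[perm, :, epoch_start_bin:]
    junction = epoch[:, :, :1]
    out = np.concatenate([pre, junction, epoch], axis=2)
    bw = rates.bin_width_ms
    time = np.concatenate([rates.time_axis_ms[:epoch_start_bin], rates.time_axis_ms[epoch_start_bin - 1 :] + bw])
    shuffled = ConditionAveragedRates(
        rates=out, bin_width_ms=bw, time_axis_ms=time, condition_labels=rates.condition_labels
    )
    return shuffled, perm, epoch_start_bin + 1


@dataclass
class ShuffleResult:
    """Original vs shuffled rotational variance fractions."""

    original_r2: float
    shuffled_r2: np.ndarray
    shuffle_kind: str
    seed: int
    n_shuffles: int

    def __post_init__(self) -> None:
        self.shuffled_r2 = np.asarray(self.shuffled_r2, dtype=float)
        if self.shuffled_r2.shape != (self.n_shuffles,):
            raise ValueError("shuffled_r2 length must equal n_shuffles")

    @property
    def mean(self) -> float:
        return float(self.shuffled_r2.mean())

    @property
    def sd(self) -> float:
        return float(self.shuffled_r2.std(ddof=1)) if self.n_shuffles > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial": np.arange(self.n_shuffles), "r2_skew": self.shuffled_r2}
        )

    def to_dict(self) -> dict:
        return {
            "shuffle_kind": self.shuffle_kind,
            "seed": self.seed,
            "n_shuffles": self.n_shuffles,
            "original_r2": self.original_r2,
            "shuffled_mean_r2": self.mean,
            "shuffled_sd_r2": self.sd,
            "shuffled_r2": self.shuffled_r2.tolist(),
        }


def smoothed_analysis_window(
    trials: TrialSet,
    kernel_sd_ms: float = 25.0,
    epoch_start_ms: float | None = None,
    epoch_len_ms: float = 250.0,
) -> tuple[ConditionAveragedRates, int]:
    """Trial-averaged, smoothed rates over the analysis window
    (recording start through epoch end), plus the epoch's start bin."""
    avg = trial_average(trials)
    sm = smooth_rates(avg, kernel_sd_ms)
    if epoch_start_ms is None:
        epoch_start_ms = float(np.median(trials.epoch_markers[:, 1]))
    t0 = sm.time_axis_ms[0]
    window = extract_epoch(sm, t0, epoch_start_ms + epoch_len_ms - t0)
    start_bin = int(round((epoch_start_ms - t0) / sm.bin_width_ms))
    return window, start_bin


def rotational_r2_for_window(
    window: ConditionAveragedRates,
    epoch_start_bin: int,
    soft_norm_constant_hz: float = 5.0,
    n_pcs: int = 6,
) -> float:
    """Full re-analysis of an analysis window: soft-normalise over the
    window, mean-center, PCA on the movement epoch (everything from the
    epoch start bin on), fit the skew model, return r2_skew."""
    norm, _ = soft_normalize(window, soft_norm_constant_hz)
    cent = mean_center(norm)
    epoch = cent.copy_with(
        cent.rates[:, :, epoch_start_bin:], time_axis_ms=cent.time_axis_ms[epoch_start_bin:]
    )
    state = reduce_dims(epoch, d=n_pcs)
    pair = make_derivative_pair(state)
    m_skew = fit_skew(pair)
    return rotational_variance_fraction(pair, m_skew).r2_skew


def run_shuffle_suite(
    trials: TrialSet,
    shuffle_kind: str,
    n_shuffles: int = 300,
    seed: int = 0,
    kernel_sd_ms: float = 25.0,
    epoch_start_ms: float | None = None,
    epoch_len_ms: float = 250.0,
    soft_norm_constant_hz: float = 5.0,
    n_pcs: int = 6,
    perm: np.ndarray | None = None,
) -> ShuffleResult:
    """Shuffle, re-analyse, repeat.

    For each of ``n_shuffles`` trials the chosen shuffle is applied to
    the smoothed pre-normalisation rates and the rotational variance
    fraction recomputed through normalisation, PCA, and the skew fit.
    ``invert_all`` is deterministic, so every trial yields the same
    value.  ``perm`` forces a fixed reassignment permutation (mainly
    for validation).
    """
    if shuffle_kind not in SHUFFLE_KINDS:
        raise ValueError(f"unknown shuffle kind {shuffle_kind!r}; choose from {SHUFFLE_KINDS}")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    window, start_bin = smoothed_analysis_window(
        trials, kernel_sd_ms=kernel_sd_ms, epoch_start_ms=epoch_start_ms, epoch_len_ms=epoch_len_ms
    )
    original = rotational_r2_for_window(
        window, start_bin, soft_norm_constant_hz=soft_norm_constant_hz, n_pcs=n_pcs
    )
    values = np.empty(n_shuffles)
    for k in range(n_shuffles):
        child = np.random.default_rng([seed, k])
        if shuffle_kind == "invert_half":
            shuffled, _ = shuffle_invert_half(window, child, epoch_start_bin=start_bin)
            sb = start_bin
        elif shuffle_kind == "invert_all":
            shuffled = shuffle_invert_all(window, epoch_start_bin=start_bin)
            sb = start_bin
        else:
            shuffled, _, sb = shuffle_reassign(window, start_bin, seed=child, perm=perm)
        values[k] = rotational_r2_for_window(
            shuffled, sb, soft_norm_constant_hz=soft_norm_constant_hz, n_pcs=n_pcs
        )
    return ShuffleResult(
        original_r2=original,
        shuffled_r2=values,
        shuffle_kind=shuffle_kind,
        seed=seed,
        n_shuffles=n_shuffles,
    )
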