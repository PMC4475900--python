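"""From raw trials to the reduced population state.

The chain follows the standard rotational-dynamics preprocessing for
trial-structured recordings:

1. average spike counts across trials within each condition and convert
   to firing rates (spikes/s);
2. smooth each electrode's rate with a Gaussian kernel (SD ~25-30 ms);
3. soft-normalise each electrode by its firing-rate range across the
   analysis window plus a constant (default 5 spikes/s), so high-rate
   electrodes do not dominate the PCA;
4. mean-center: subtract the cross-condition mean response at each
   (electrode, time);
5. restrict to the 250 ms movement epoch beginning at the rapid
   pre-movement change in activity;
6. reduce to the top d principal components (default d = 6),
   giving the state matrix ``X_red`` of shape d x (C*T).

Pre-movement states (the dynamical system's initial conditions, used to
orient jPCA planes) are the mean of the last few pre-epoch bins of the
normalised, centered data projected into the same PCA basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datasets import TrialSet, ConditionAveragedRates, StateMatrix

__all__ = [
    "trial_average",
    "smooth_rates",
    "extract_epoch",
    "detect_epoch_start",
    "soft_normalize",
    "mean_center",
    "reduce_dims",
    "preprocess",
    "PreprocessResult",
]


def trial_average(trials: TrialSet) -> ConditionAveragedRates:
    """Mean count per bin across trials of each condition, divided by
    the bin width: a C x E x T array of rates in spikes/s."""
    c = trials.n_conditions
    if c < 1:
        raise ValueError("TrialSet has no trials")
    dt_s = trials.bin_width_ms / 1000.0
    rates = np.empty((c, trials.n_electrodes, trials.n_bins))
    for ci in range(c):
        sel = trials.condition == ci
        if not np.any(sel):
            raise ValueError(f"condition {ci} has zero trials")
        rates[ci] = trials.counts[sel].mean(axis=0) / dt_s
    time_axis = np.arange(trials.n_bins) * trials.bin_width_ms
    return ConditionAveragedRates(
        rates=rates, bin_width_ms=trials.bin_width_ms, time_axis_ms=time_axis
    )


def smooth_rates(rates: ConditionAveragedRates, kernel_sd_ms: float) -> ConditionAveragedRates:
    """Convolve each (condition, electrode) series with a unit-area
    Gaussian kernel truncated at +/-4 SD, reflecting at the boundaries.

    The kernel has unit sum, so constant series pass unchanged and total
    rate mass is conserved for interior-supported signals.
    """
    if kernel_sd_ms <= 0:
        raise ValueError("kernel_sd_ms must be positive")
    if kernel_sd_ms < rates.bin_width_ms / 2:
        warnings.warn(
            f"kernel SD {kernel_sd_ms} ms is under-resolved at "
            f"{rates.bin_width_ms} ms bins"
        )
    sigma_bins = kernel_sd_ms / rates.bin_width_ms
    sm = ndimage.gaussian_filter1d(
        rates.rates, sigma=sigma_bins, axis=-1, mode="reflect", truncate=4.0
    )
    return rates.copy_with(sm)


def extract_epoch(
    rates: ConditionAveragedRates, epoch_start_ms: float, epoch_len_ms: float = 250.0
) -> ConditionAveragedRates:
    """Half-open window ``[start, start + len)`` on the time axis;
    the returned bin count is ``len / bin_width``."""
    bw = rates.bin_width_ms
    t0 = rates.time_axis_ms[0]
    start_bin = (epoch_start_ms - t0) / bw
    n_bins = epoch_len_ms / bw
    if abs(start_bin - round(start_bin)) > 1e-6 or abs(n_bins - round(n_bins)) > 1e-6:
        raise ValueError("epoch window must align with bin edges")
    start_bin, n_bins = int(round(start_bin)), int(round(n_bins))
    if start_bin < 0 or start_bin + n_bins > rates.n_bins:
        raise ValueError(
            f"epoch [{epoch_start_ms}, {epoch_start_ms + epoch_len_ms}) ms exceeds "
            f"recorded range [{t0}, {t0 + rates.n_bins * bw}) ms"
        )
    sl = slice(start_bin, start_bin + n_bins)
    return rates.copy_with(rates.rates[:, :, sl], time_axis_ms=rates.time_axis_ms[sl])


def detect_epoch_start(rates: ConditionAveragedRates, back_off_ms: float = 0.0) -> float:
    """Heuristic epoch onset from the population rate-of-change norm.

    The score is ``sum_c ||delta r||`` per bin transition; the onset is
    the first bin where the score rises halfway from its baseline
    (median) to its maximum, minus ``back_off_ms``.  The half-rise
    criterion localises the onset even when the post-onset speed is a
    plateau (as for constant-speed rotations, where a plain argmax is
    ill-posed); for an isolated step change it coincides with the
    argmax.  Intended as an optional helper — analyses normally take
    the epoch start from explicit configuration.
    """
    dr = np.diff(rates.rates, axis=-1)  # (C, E, T-1)
    score = np.sqrt((dr**2).sum(axis=1)).sum(axis=0)  # (T-1,)
    if score.size == 0 or score.max() <= 1e-12:
        warnings.warn("rates are flat; returning epoch start 0")
        return 0.0
    baseline = float(np.quantile(score, 0.25))
    thr = baseline + 0.5 * (score.max() - baseline)
    k = int(np.argmax(score >= thr))
    if k > 0 and score[k] > score[k - 1]:
        # sub-bin crossing by linear interpolation, then nearest bin
        kc = k - 1 + (thr - score[k - 1]) / (score[k] - score[k - 1])
        k = int(np.floor(kc + 0.5))
    return float(rates.time_axis_ms[k + 1] - back_off_ms)


def soft_normalize(
    rates: ConditionAveragedRates, constant_hz: float = 5.0
) -> tuple[ConditionAveragedRates, dict]:
    """Divide each electrode's series by (its rate range across all
    conditions and times + ``constant_hz``).

    The constant keeps the divisor positive for silent electrodes and
    shrinks low-rate channels; returns the normalised rates and a record
    of the per-electrode range and constant used.
    """
    if constant_hz < 0:
        raise ValueError("constant_hz must be non-negative")
    rng_e = rates.rates.max(axis=(0, 2)) - rates.rates.min(axis=(0, 2))  # (E,)
    divisor = rng_e + constant_hz
    if np.any(divisor <= 0):
        raise ValueError("zero divisor: constant_hz=0 with a constant electrode")
    out = rates.copy_with(rates.rates / divisor[None, :, None])
    record = {"range_hz": rng_e, "constant_hz": constant_hz, "divisor": divisor}
    return out, record


def mean_center(rates: ConditionAveragedRates) -> ConditionAveragedRates:
    """Subtract the cross-condition mean at every (electrode, time),
    removing the condition-independent response component."""
    if rates.n_conditions < 2:
        raise ValueError("mean-centering requires >= 2 conditions")
    return rates.copy_with(rates.rates - rates.rates.mean(axis=0, keepdims=True))


def reduce_dims(
    rates: ConditionAveragedRates, d: int = 6, normalization_record: dict | None = None
) -> StateMatrix:
    """PCA on the E x (C*T) matrix of concatenated condition blocks.

    Each condition-time sample is one observation; the sample mean is
    removed and the data projected onto the top ``d`` components.
    """
    c, e, t = rates.rates.shape
    if d > min(e, c * t):
        raise ValueError(f"d={d} exceeds min(n_electrodes, n_samples)")
    z = np.concatenate([rates.rates[ci] for ci in range(c)], axis=1)  # (E, C*T)
    mean = z.mean(axis=1)
    zc = z - mean[:, None]
    u, s, _ = np.linalg.svd(zc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if d > rank:
        raise ValueError(f"d={d} exceeds data rank {rank}")
    # deterministic sign convention: largest-|.| component of each PC positive
    for j in range(d):
        i = np.argmax(np.abs(u[:, j]))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
    basis = u[:, :d]
    total = float(np.sum(s**2))
    return StateMatrix(
        X_red=basis.T @ zc,
        pca_basis=basis,
        per_dim_variance=(s[:d] ** 2) / total,
        n_conditions=c,
        n_timebins=t,
        bin_width_ms=rates.bin_width_ms,
        d=d,
        epoch_window_ms=(float(rates.time_axis_ms[0]), float(t * rates.bin_width_ms)),
        pca_mean=mean,
        total_variance=total,
        normalization_record=normalization_record,
    )


@dataclass
class PreprocessResult:
    """Everything downstream stages need: the reduced state, the
    pre-movement initial states, and the normalised/centered
    electrode-space rates over the full analysis window."""

    state: StateMatrix
    pre_movement_states: np.ndarray  # (C, d)
    window_rates: ConditionAveragedRates
    epoch_start_bin: int
    params: dict


def preprocess(
    trials: TrialSet,
    kernel_sd_ms: float = 25.0,
    epoch_start_ms: float | str | None = None,
    epoch_len_ms: float = 250.0,
    soft_norm_constant_hz: float = 5.0,
    n_pcs: int = 6,
    pre_window_bins: int = 5,
    channel_mask: np.ndarray | None = None,
    back_off_ms: float = 0.0,
) -> PreprocessResult:
    """Run the full preprocessing chain on a TrialSet.

    ``epoch_start_ms`` may be a number (explicit configuration, the
    default route), ``None`` (use the trial epoch markers' median), or
    ``"detect"`` (rate-of-change heuristic).  The soft-normalisation
    range is computed over the analysis window (recording start through
    epoch end); PCA uses movement-epoch samples only, and pre-movement
    states are projected into that basis.
    """
    avg = trial_average(trials)
    if channel_mask is not None:
        channel_mask = np.asarray(channel_mask)
        avg = ConditionAveragedRates(
            rates=avg.rates[:, channel_mask, :],
            bin_width_ms=avg.bin_width_ms,
            time_axis_ms=avg.time_axis_ms,
        )
    sm = smooth_rates(avg, kernel_sd_ms)

    if epoch_start_ms is None:
        epoch_start_ms = float(np.median(trials.epoch_markers[:, 1]))
    elif epoch_start_ms == "detect":
        epoch_start_ms = detect_epoch_start(sm, back_off_ms=back_off_ms)
    epoch_start_ms = float(epoch_start_ms)

    window = extract_epoch(sm, sm.time_axis_ms[0], epoch_start_ms + epoch_len_ms - sm.time_axis_ms[0])
    norm, record = soft_normalize(window, soft_norm_constant_hz)
    cent = mean_center(norm)
    epoch = extract_epoch(cent, epoch_start_ms, epoch_len_ms)
    state = reduce_dims(epoch, d=n_pcs, normalization_record=record)

    bw = cent.bin_width_ms
    epoch_start_bin = int(round((epoch_start_ms - cent.time_axis_ms[0]) / bw))
    lo = max(0, epoch_start_bin - pre_window_bins)
    if epoch_start_bin > 0:
        pre_block = cent.rates[:, :, lo:epoch_start_bin].mean(axis=2)  # (C, E)
    else:
        pre_block = cent.rates[:, :, 0]
    pre_states = (pre_block - state.pca_mean[None, :]) @ state.pca_basis  # (C, d)

    params = dict(
        kernel_sd_ms=kernel_sd_ms,
        epoch_start_ms=epoch_start_ms,
        epoch_len_ms=epoch_len_ms,
        soft_norm_constant_hz=soft_norm_constant_hz,
        n_pcs=n_pcs,
        pre_window_bins=pre_window_bins,
    )
    return PreprocessResult(
        state=state,
        pre_movement_states=pre_states,
        window_rates=cent,
        epoch_start_bin=epoch_start_bin,
        params=params,
    )
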