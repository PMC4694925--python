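"""Spike-train and weight statistics.

Covers the basic characterization of the self-organized network (inter-spike
intervals and their coefficient of variation, connection-fraction traces,
lognormal weight fits), the trial-aligned Fano-factor analysis with causal
sliding windows and mean matching, and the conditional firing probabilities
that link the learned weights to the spontaneous dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .network import SpikeRecording

__all__ = [
    "TrialTensor",
    "FanoCurve",
    "ConditionalProbabilityFit",
    "IsiStats",
    "LognormalWeightFit",
    "isi_cv_stats",
    "connection_fraction",
    "fit_lognormal_weights",
    "fano_curve",
    "mean_matched_fano",
    "conditional_firing_probabilities",
]


# ---------------------------------------------------------------------------
# trial alignment
# ---------------------------------------------------------------------------

@dataclass
class TrialTensor:
    """Stimulus-onset-aligned binary activity, trials x time x neurons.

    The time axis covers offsets ``-pre .. +post`` relative to onset plus a
    leading ``margin`` so that causal sliding-window counts are defined at
    the earliest offset.  ``input_units`` marks units receiving direct
    sensory input (excluded from Fano-factor analyses).
    """

    spikes: np.ndarray                # (n_trials, margin+pre+post+1, n_neurons) uint8
    onset_index: int                  # index of the onset step on the time axis
    pre: int
    post: int
    margin: int
    conditions: np.ndarray            # (n_trials,) labels
    input_units: np.ndarray           # (n_neurons,) bool
    kept_trials: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.intp))

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.pre, self.post + 1)

    def state_at(self, offset: int) -> np.ndarray:
        """States at ``onset + offset`` for every trial."""
        idx = self.onset_index + offset
        if idx < 0 or idx >= self.spikes.shape[1]:
            raise IndexError(f"offset {offset} outside the recorded window")
        return self.spikes[:, idx, :]

    def windowed_counts(self, window: int = 5) -> tuple[np.ndarray, np.ndarray]:
        """Causal sliding-window spike counts and the offsets they cover."""
        if window > self.margin + 1:
            warnings.warn(
                f"window {window} exceeds the pre-onset margin; "
                "earliest offsets are truncated"
            )
        c = np.cumsum(self.spikes, axis=1, dtype=np.int32)
        zeros = np.zeros_like(c[:, :1, :])
        c = np.concatenate([zeros, c], axis=1)
        lo = max(self.onset_index - self.pre, window - 1)
        hi = self.onset_index + self.post
        idx = np.arange(lo, hi + 1)
        counts = c[:, idx + 1, :] - c[:, idx + 1 - window, :]
        return counts, idx - self.onset_index

    def subset(self, condition) -> "TrialTensor":
        sel = np.flatnonzero(self.conditions == condition)
        return TrialTensor(
            spikes=self.spikes[sel], onset_index=self.onset_index, pre=self.pre,
            post=self.post, margin=self.margin, conditions=self.conditions[sel],
            input_units=self.input_units, kept_trials=self.kept_trials[sel]
            if self.kept_trials.size else self.kept_trials,
        )

    @classmethod
    def from_recording(
        cls,
        recording: SpikeRecording,
        onsets: np.ndarray,
        pre: int,
        post: int,
        conditions: np.ndarray,
        input_units: np.ndarray,
        margin: int = 4,
    ) -> "TrialTensor":
        """Cut aligned windows from a continuous recording.

        Trials whose window (including the margin) falls outside the
        recording are dropped; ``kept_trials`` holds the surviving indices.
        """
        onsets = np.asarray(onsets)
        T = recording.n_steps
        ok = (onsets - pre - margin >= 0) & (onsets + post < T)
        kept = np.flatnonzero(ok)
        width = margin + pre + post + 1
        tensor = np.zeros((kept.size, width, recording.spikes.shape[1]), dtype=np.uint8)
        for k, tr in enumerate(kept):
            start = onsets[tr] - pre - margin
            tensor[k] = recording.spikes[start : start + width]
        mask = np.zeros(recording.spikes.shape[1], dtype=bool)
        mask[np.asarray(input_units, dtype=np.intp)] = True
        return cls(
            spikes=tensor, onset_index=margin + pre, pre=pre, post=post,
            margin=margin, conditions=np.asarray(conditions)[kept],
            input_units=mask, kept_trials=kept,
        )


# ---------------------------------------------------------------------------
# Fano factors
# ---------------------------------------------------------------------------

@dataclass
class FanoCurve:
    """Population Fano factor per offset (weighted variance-on-mean slope)."""

    offsets: np.ndarray
    ff: np.ndarray
    mean_rate: np.ndarray
    matched_ff: Optional[np.ndarray] = None
    fraction_discarded: Optional[float] = None
    window: int = 5


def _regression_ff(means: np.ndarray, variances: np.ndarray) -> float:
    """Weighted regression of variance on mean through the origin.

    Weights are the inverse of the asymptotic variance of the sample
    variance, which scales with the squared mean, so the slope equals the
    precision-weighted average of the per-point variance/mean ratios.
    """
    ok = means > 1e-12
    if not ok.any():
        return np.nan
    m, v = means[ok], variances[ok]
    w = 1.0 / m ** 2
    return float(np.sum(w * m * v) / np.sum(w * m ** 2))


def fano_curve(
    trials: TrialTensor,
    window: int = 5,
    condition=None,
) -> FanoCurve:
    """Trial-to-trial Fano factor around stimulus onset.

    Counts are causal sliding-window sums of width ``window``; mean and
    variance are taken over trials per neuron and offset, restricted to
    units that receive no direct sensory input; the population FF at each
    offset is the weighted regression slope of variance on mean.
    """
    if condition is not None:
        trials = trials.subset(condition)
    if trials.n_trials < 2:
        raise ValueError("need at least two trials for a variance")
    counts, offsets = trials.windowed_counts(window)
    counts = counts[:, :, ~trials.input_units].astype(float)
    means = counts.mean(axis=0)
    variances = counts.var(axis=0, ddof=1)
    ff = np.array([_regression_ff(means[k], variances[k]) for k in range(offsets.size)])
    return FanoCurve(offsets=offsets, ff=ff, mean_rate=means.mean(axis=1), window=window)


def mean_matched_fano(
    trials_by_condition: Sequence[TrialTensor] | TrialTensor,
    window: int = 5,
    bin_width: float = 0.2,
    n_iter: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> FanoCurve:
    """Fano factor after equalizing the mean-count distribution over offsets.

    Data points are (neuron, condition) pairs.  The greatest common
    distribution of windowed mean counts is the bin-wise minimum of the
    per-offset histograms (bin width ``bin_width``); at every offset points
    are randomly discarded until its histogram matches, the regression FF is
    recomputed from the survivors, and the result is averaged over
    ``n_iter`` discard randomizations.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(trials_by_condition, TrialTensor):
        tensors = [trials_by_condition.subset(c)
                   for c in np.unique(trials_by_condition.conditions)]
    else:
        tensors = list(trials_by_condition)
    if not tensors:
        raise ValueError("no conditions supplied")

    mean_list, var_list = [], []
    offsets = None
    for t in tensors:
        counts, offs = t.windowed_counts(window)
        counts = counts[:, :, ~t.input_units].astype(float)
        if offsets is None:
            offsets = offs
        elif not np.array_equal(offsets, offs):
            raise ValueError("conditions must share the same offsets")
        mean_list.append(counts.mean(axis=0))
        var_list.append(counts.var(axis=0, ddof=1))
    means = np.concatenate(mean_list, axis=1)      # (n_offsets, n_points)
    variances = np.concatenate(var_list, axis=1)

    edges = np.arange(0.0, means.max() + 2 * bin_width, bin_width)
    bins = np.clip(np.digitize(means, edges) - 1, 0, edges.size - 2)
    hists = np.stack([np.bincount(bins[k], minlength=edges.size - 1)
                      for k in range(offsets.size)])
    common = hists.min(axis=0)
    if common.sum() == 0:
        raise ValueError("greatest common mean distribution is empty")

    n_points = means.shape[1]
    ff_iters = np.zeros((n_iter, offsets.size))
    raw_ff = np.array([_regression_ff(means[k], variances[k])
                       for k in range(offsets.size)])
    for it in range(n_iter):
        for k in range(offsets.size):
            keep = []
            for b in np.flatnonzero(common):
                members = np.flatnonzero(bins[k] == b)
                take = common[b]
                if members.size > take:
                    members = rng.choice(members, size=take, replace=False)
                keep.append(members)
            keep = np.concatenate(keep)
            ff_iters[it, k] = _regression_ff(means[k][keep], variances[k][keep])
    fraction = 1.0 - common.sum() / n_points
    return FanoCurve(
        offsets=offsets, ff=raw_ff,
        mean_rate=means.mean(axis=1),
        matched_ff=ff_iters.mean(axis=0),
        fraction_discarded=float(fraction), window=window,
    )


# ---------------------------------------------------------------------------
# ISI / CV statistics
# ---------------------------------------------------------------------------

@dataclass
class IsiStats:
    cvs: np.ndarray                   # per-neuron CV (neurons with >= min ISIs)
    isis: np.ndarray                  # pooled ISIs
    exp_scale: float                  # ML scale of the exponential tail fit
    exp_cutoff: int
    ks_statistic: float
    n_excluded: int


def isi_cv_stats(
    recording: SpikeRecording, min_isis: int = 10, cutoff: int = 2
) -> IsiStats:
    """Inter-spike-interval distribution and per-neuron CV of the ISIs.

    The pooled ISI distribution is fitted by maximum likelihood with an
    exponential above a small-ISI cutoff (the model deviates from the
    exponential only at very small intervals).  Silent or nearly silent
    neurons (fewer than ``min_isis`` ISIs) are excluded and counted.
    """
    spikes = recording.spikes
    cvs, pooled = [], []
    n_excluded = 0
    for i in range(spikes.shape[1]):
        times = np.flatnonzero(spikes[:, i])
        isis = np.diff(times)
        if isis.size < min_isis:
            n_excluded += 1
            continue
        pooled.append(isis)
        cvs.append(isis.std() / isis.mean())
    pooled = np.concatenate(pooled) if pooled else np.zeros(0, dtype=int)
    tail = pooled[pooled > cutoff] - cutoff
    if tail.size:
        scale = float(tail.mean())  # ML estimate of the exponential scale
        ks = float(scipy.stats.kstest(tail, "expon", args=(0, scale)).statistic)
    else:
        scale, ks = np.nan, np.nan
    return IsiStats(
        cvs=np.asarray(cvs), isis=pooled, exp_scale=scale, exp_cutoff=cutoff,
        ks_statistic=ks, n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def connection_fraction(weight_snapshots: Sequence[np.ndarray]) -> np.ndarray:
    """Fraction of nonzero off-diagonal E->E entries per snapshot."""
    snaps = list(weight_snapshots)
    if len(snaps) < 2:
        raise ValueError("need at least two snapshots for a trace")
    out = np.zeros(len(snaps))
    for k, w in enumerate(snaps):
        n = w.shape[0]
        out[k] = (np.count_nonzero(w) - np.count_nonzero(np.diagonal(w))) / (n * (n - 1))
    return out


@dataclass
class LognormalWeightFit:
    mu: float
    sigma: float
    ks_lognormal: float
    ks_normal: float
    n_weights: int


def fit_lognormal_weights(w_ee: np.ndarray, min_weights: int = 100) -> LognormalWeightFit:
    """ML lognormal fit to the nonzero weights, with KS goodness-of-fit.

    The KS statistic of a plain normal fit is reported alongside for
    comparison (the lognormal should win on a self-organized matrix).
    """
    w = np.asarray(w_ee)
    w = w[w > 0]
    if w.size < min_weights:
        raise ValueError(f"need at least {min_weights} nonzero weights, got {w.size}")
    sigma, _, scale = scipy.stats.lognorm.fit(w, floc=0)
    mu = float(np.log(scale))
    ks_ln = float(scipy.stats.kstest(w, "lognorm", args=(sigma, 0, scale)).statistic)
    loc, sd = scipy.stats.norm.fit(w)
    ks_n = float(scipy.stats.kstest(w, "norm", args=(loc, sd)).statistic)
    return LognormalWeightFit(mu=mu, sigma=float(sigma), ks_lognormal=ks_ln,
                              ks_normal=ks_n, n_weights=int(w.size))


# ---------------------------------------------------------------------------
# conditional firing probabilities
# ---------------------------------------------------------------------------

@dataclass
class ConditionalProbabilityFit:
    """p(x_i(t+1)=1 | x_j(t)=1) against W_ij for every existing synapse."""

    weights: np.ndarray
    probabilities: np.ndarray
    kappa: float                      # proportionality below saturation
    pearson_r: float                  # correlation below saturation
    saturation_weight: float
    n_skipped: int                    # synapses with a silent presynaptic unit


def conditional_firing_probabilities(
    recording: SpikeRecording,
    w_ee: np.ndarray,
    conn: Optional[np.ndarray] = None,
    saturation_quantile: float = 0.95,
) -> ConditionalProbabilityFit:
    """Empirical one-step conditional firing probabilities per synapse.

    Computed on spontaneous activity (no input) so that the probabilities
    reflect the recurrent dynamics alone.  The proportionality constant
    kappa is fitted by least squares through the origin over synapses below
    the saturation regime (weights above the ``saturation_quantile`` are
    excluded from the fit).
    """
    spikes = recording.spikes.astype(np.float64)
    pre = spikes[:-1]
    post = spikes[1:]
    joint = post.T @ pre                          # counts of j->i spike pairs
    pre_counts = pre.sum(axis=0)
    mask = (np.asarray(conn) if conn is not None else (w_ee > 0)).copy()
    np.fill_diagonal(mask, False)
    ii, jj = np.nonzero(mask)
    alive = pre_counts[jj] > 0
    n_skipped = int((~alive).sum())
    ii, jj = ii[alive], jj[alive]
    probs = joint[ii, jj] / pre_counts[jj]
    weights = w_ee[ii, jj]
    cut = np.quantile(weights, saturation_quantile) if weights.size else np.nan
    sub = weights <= cut
    if sub.sum() >= 2 and np.ptp(weights[sub]) > 0:
        kappa = float(np.sum(weights[sub] * probs[sub]) / np.sum(weights[sub] ** 2))
        r = float(scipy.stats.pearsonr(weights[sub], probs[sub]).statistic)
    else:
        kappa, r = np.nan, np.nan
    return ConditionalProbabilityFit(
        weights=weights, probabilities=probs, kappa=kappa, pearson_r=r,
        saturation_weight=float(cut), n_skipped=n_skipped,
    )
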