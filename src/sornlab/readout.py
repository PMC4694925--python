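"""Least-squares linear readouts: network decisions and their prediction.

The network "decision" in the inference task is the argmax of two linear
readouts applied to the excitatory state at the first blank after the mask.
Readouts are trained by ordinary least squares (with an appended constant
bias regressor) on the training phase, where the cue is unambiguous.

The same regression machinery predicts evoked activity and decisions from
the spontaneous state prior to stimulus onset, with trial-shuffled controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import SpikeRecording

__all__ = [
    "LinearReadout",
    "parse_trials",
    "fit_decision_readout",
    "decide",
    "predict_evoked_activity",
    "evoked_prediction_curve",
    "predict_decisions",
]


@dataclass
class LinearReadout:
    """Linear map from (state, 1) to class scores; last weight row is the bias."""

    weights: np.ndarray               # (n_features + 1, n_classes)
    classes: tuple

    def scores(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(states)
        return states @ self.weights[:-1] + self.weights[-1]


def _lstsq(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Min-norm least squares with an appended bias column."""
    Xb = np.column_stack([X, np.ones(X.shape[0])])
    if Xb.shape[0] < Xb.shape[1]:
        warnings.warn(
            f"underdetermined regression ({Xb.shape[0]} samples, "
            f"{Xb.shape[1]} regressors); using the pseudoinverse solution",
            stacklevel=3,
        )
    W, *_ = np.linalg.lstsq(Xb, Y, rcond=None)
    return W


def parse_trials(
    recording: SpikeRecording,
    mask_len: int = 3,
    cue_letters: Sequence[str] = ("A", "B"),
) -> pd.DataFrame:
    """Recover trial structure (onset, decision step, cue) from the letters.

    A trial starts at a cue letter that follows a blank (or the recording
    start); the decision step is the first blank after the ``mask_len``-step
    mask.  Incomplete trials at the end are dropped.
    """
    letters = recording.letters
    T = letters.shape[0]
    cue_set = set(cue_letters) | {"A/B"}
    rows = []
    for t in range(T):
        if letters[t] in cue_set and (t == 0 or letters[t - 1] == "_"):
            dec = t + mask_len + 1
            if dec < T and letters[dec] == "_":
                rows.append((t, dec, letters[t]))
    return pd.DataFrame(rows, columns=["onset", "decision_step", "cue"])


def fit_decision_readout(
    recording: SpikeRecording,
    mask_len: int = 3,
    cue_letters: Sequence[str] = ("A", "B"),
    rng: Optional[np.random.Generator] = None,
) -> LinearReadout:
    """Train the two decision regressions on an unambiguous training phase.

    The regressors are the states at the first blank after the mask; the
    target for readout "A" is 1 on A-trials and 0 otherwise (and symmetrically
    for "B").  States evoked by the individual letters (cues and mask) enter
    with target 0 for both readouts.  Sampling is balanced in two ways,
    regardless of the training prior: the two decision categories contribute
    the same number of samples (so each classifier sees as many positive as
    negative decision states), and the letter categories contribute equal
    shares of the remaining, always-negative samples.
    """
    letters = recording.letters
    trials = parse_trials(recording, mask_len=mask_len, cue_letters=cue_letters)
    a, b = cue_letters
    decision_cats = {}
    for cue in (a, b):
        steps = trials.loc[trials["cue"] == cue, "decision_step"].to_numpy()
        if steps.size == 0:
            raise ValueError(f"no {cue!r} trials in the training recording")
        decision_cats[cue] = steps
    letter_pool = sorted(set(np.unique(letters)) - {"_"})
    letter_cats = {c: np.flatnonzero(letters == c) for c in letter_pool}

    n = min(v.size for v in decision_cats.values())
    # each readout sees n positive decision states, n opposite decision
    # states and ~n letter states (always negative), split evenly per letter
    m = max(1, n // len(letter_cats))
    m = min(m, min(v.size for v in letter_cats.values()))
    states, ya, yb = [], [], []
    for cue, steps in decision_cats.items():
        take = steps[-n:]
        states.append(recording.spikes[take].astype(float))
        ya.append(np.full(n, 1.0 if cue == a else 0.0))
        yb.append(np.full(n, 1.0 if cue == b else 0.0))
    for letter, steps in letter_cats.items():
        take = steps[-m:]
        states.append(recording.spikes[take].astype(float))
        ya.append(np.zeros(m))
        yb.append(np.zeros(m))
    X = np.vstack(states)
    Y = np.column_stack([np.concatenate(ya), np.concatenate(yb)])
    W = _lstsq(X, Y)
    return LinearReadout(weights=W, classes=(a, b))


def decide(readout: LinearReadout, state: np.ndarray) -> str:
    """Argmax of the readout scores; exact ties resolve to the first class."""
    s = readout.scores(np.asarray(state, dtype=float))[0]
    return readout.classes[0] if s[0] >= s[1] else readout.classes[1]


# ---------------------------------------------------------------------------
# predictions from pre-stimulus spontaneous activity
# ---------------------------------------------------------------------------

def _trial_split(n: int) -> tuple[np.ndarray, np.ndarray]:
    half = n // 2
    return np.arange(half), np.arange(half, n)


def _mean_trial_correlation(pred: np.ndarray, actual: np.ndarray) -> float:
    """Average Pearson correlation between predicted and actual state vectors."""
    pc = pred - pred.mean(axis=1, keepdims=True)
    ac = actual - actual.mean(axis=1, keepdims=True)
    num = (pc * ac).sum(axis=1)
    den = np.sqrt((pc ** 2).sum(axis=1) * (ac ** 2).sum(axis=1))
    valid = den > 0
    if not valid.any():
        return np.nan
    return float((num[valid] / den[valid]).mean())


def predict_evoked_activity(
    trials,
    offsets: Optional[Sequence[int]] = None,
    shuffle: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Predict evoked states from the pre-onset spontaneous state, per offset.

    For every condition, a least-squares map (with bias) from the state one
    step before stimulus onset to the state at onset + offset is fitted on
    the first half of the trials and evaluated on the second half; reported
    is the mean Pearson correlation between predicted and actual states over
    held-out trials, pooled across conditions.  ``shuffle=True`` permutes the
    pre-onset states across trials within each condition, which destroys the
    trial-specific information while keeping the bias term (the
    stimulus-average response).
    """
    if shuffle and rng is None:
        raise ValueError("shuffle=True requires an rng")
    if offsets is None:
        offsets = np.arange(0, trials.offsets.max() + 1)
    offsets = np.asarray(offsets, dtype=int)
    rows = []
    for dt in offsets:
        corrs = []
        weights = []
        for cond in np.unique(trials.conditions):
            sel = np.flatnonzero(trials.conditions == cond)
            pre = trials.state_at(-1)[sel].astype(float)
            target = trials.state_at(dt)[sel].astype(float)
            if shuffle:
                pre = pre[rng.permutation(sel.size)]
            tr, te = _trial_split(sel.size)
            if tr.size < 2 or te.size < 2:
                continue
            W = _lstsq(pre[tr], target[tr])
            pred = np.column_stack([pre[te], np.ones(te.size)]) @ W
            c = _mean_trial_correlation(pred, target[te])
            if np.isfinite(c):
                corrs.append(c)
                weights.append(te.size)
        rows.append((int(dt), float(np.average(corrs, weights=weights))
                     if corrs else np.nan))
    return pd.DataFrame(rows, columns=["offset", "correlation"])


def evoked_prediction_curve(
    trials, offsets=None, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Unshuffled prediction curve and its trial-shuffled baseline."""
    if rng is None:
        rng = np.random.default_rng()
    real = predict_evoked_activity(trials, offsets, shuffle=False)
    base = predict_evoked_activity(trials, offsets, shuffle=True, rng=rng)
    return real.merge(base, on="offset", suffixes=("", "_shuffled"))


def predict_decisions(
    trials,
    decisions: Sequence[str],
    offsets: Sequence[int],
    shuffle: bool = False,
    rng: Optional[np.random.Generator] = None,
    min_trials: int = 10,
) -> pd.DataFrame:
    """Predict the per-trial decision from activity around stimulus onset.

    A separate two-target regression is trained for every (ambiguity class,
    offset) pair on the first half of that class's trials and scored as the
    agreement with the actual decisions on the second half.  Classes with
    fewer than ``min_trials`` trials are excluded (with a warning).
    ``shuffle=True`` permutes the states across trials within a class; the
    baseline can still exceed 50% through the bias term whenever the
    decisions are biased.
    """
    if shuffle and rng is None:
        raise ValueError("shuffle=True requires an rng")
    decisions = np.asarray(decisions)
    rows = []
    for cond in np.unique(trials.conditions):
        sel = np.flatnonzero(trials.conditions == cond)
        if sel.size < min_trials:
            warnings.warn(f"ambiguity class {cond!r} has only {sel.size} trials; excluded")
            continue
        dec = decisions[sel]
        labels = np.unique(dec)
        Y = np.column_stack([(dec == lab).astype(float) for lab in labels])
        tr, te = _trial_split(sel.size)
        for dt in offsets:
            states = trials.state_at(int(dt))[sel].astype(float)
            if shuffle:
                states = states[rng.permutation(sel.size)]
            W = _lstsq(states[tr], Y[tr])
            scores = np.column_stack([states[te], np.ones(te.size)]) @ W
            pred = labels[np.argmax(scores, axis=1)]
            rows.append((cond, int(dt), float((pred == dec[te]).mean()), te.size))
    return pd.DataFrame(rows, columns=["condition", "offset", "accuracy", "n_test"])
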