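"""State-space geometry of spontaneous and evoked activity.

All comparisons between binary population states use the Hamming distance.
Evoked states are the states recorded immediately after a letter
presentation; spontaneous states come from input-free activity sustained by
intrinsic plasticity.  The analyses here quantify how closely the
spontaneous activity outlines the learned evoked repertoire: low-dimensional
projections (PCA on evoked states, nonmetric MDS on pooled distances),
nearest-state distances against a time-shuffled control, the KL divergence
between pattern distributions of a unit subsample, decoding of spontaneous
states through a balanced evoked pattern dictionary, and letter-transition
structure both measured empirically and predicted from the SVD of the
recurrent weight matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import MDS

__all__ = [
    "PatternDictionary",
    "TransitionMatrix",
    "PcaProjection",
    "MdsEmbedding",
    "evoked_states_from_recording",
    "shuffle_spike_trains",
    "pca_project",
    "mds_outline",
    "nearest_state_distances",
    "kl_evoked_vs_spontaneous",
    "build_pattern_dictionary",
    "assign_letters",
    "word_letter_frequencies",
    "svd_transition_prediction",
    "empirical_transitions",
]

BLANK = "_"


# ---------------------------------------------------------------------------
# helpers and containers
# ---------------------------------------------------------------------------

def evoked_states_from_recording(recording, last: int = 2500):
    """Letter-labelled evoked states from the end of a recording (blanks kept)."""
    spikes = recording.spikes[-last:]
    letters = recording.letters[-last:]
    return spikes, letters


def shuffle_spike_trains(spikes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each neuron's spike train independently over time.

    Neurons keep their firing rate but lose their timing; used as the
    control set for the spontaneous-outline analyses.
    """
    out = spikes.copy()
    for i in range(out.shape[1]):
        out[:, i] = out[rng.permutation(out.shape[0]), i]
    return out


@dataclass
class PatternDictionary:
    """Balanced letter-labelled evoked states used to decode spontaneous ones."""

    evoked_states: np.ndarray         # (M, n_exc) uint8, ordered by letter
    letters: np.ndarray               # (M,) labels
    alphabet: list


@dataclass
class TransitionMatrix:
    letters: list
    probabilities: np.ndarray         # row-stochastic over observed successors
    counts: Optional[np.ndarray] = None


@dataclass
class PcaProjection:
    evoked: np.ndarray
    spontaneous: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray


@dataclass
class MdsEmbedding:
    coordinates: np.ndarray           # (3 * n_points, 2)
    labels: np.ndarray                # "spontaneous" / "shuffled" / "evoked"
    stress: float
    converged: bool


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def pca_project(
    evoked_states: np.ndarray,
    spontaneous_states: np.ndarray,
    n_components: int = 3,
) -> PcaProjection:
    """Project both state sets onto the principal components of the evoked set.

    Components are fitted on the (mean-centered, unscaled) evoked states
    only; the explained-variance fractions refer to the evoked variance.
    """
    evoked = np.asarray(evoked_states, dtype=float)
    if evoked.shape[0] < n_components:
        raise ValueError("fewer evoked states than components")
    pca = PCA(n_components=n_components)
    ev_proj = pca.fit_transform(evoked)
    sp_proj = pca.transform(np.asarray(spontaneous_states, dtype=float))
    return PcaProjection(
        evoked=ev_proj, spontaneous=sp_proj,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
    )


def mds_outline(
    spontaneous: np.ndarray,
    shuffled_spontaneous: np.ndarray,
    evoked_subset: np.ndarray,
    n_points: int = 150,
    rng: Optional[np.random.Generator] = None,
    max_iter: int = 300,
) -> MdsEmbedding:
    """Joint 2-D nonmetric MDS of spontaneous, shuffled and evoked states.

    All pairwise Hamming distances of the pooled ``3 * n_points`` states are
    embedded by nonmetric MDS minimizing Kruskal's normalized stress-1.
    """
    if rng is None:
        rng = np.random.default_rng()
    sets = []
    for arr in (spontaneous, shuffled_spontaneous, evoked_subset):
        arr = np.asarray(arr)
        if arr.shape[0] < n_points:
            raise ValueError(f"need at least {n_points} states per set")
        sets.append(arr[rng.choice(arr.shape[0], size=n_points, replace=False)])
    pooled = np.vstack(sets).astype(float)
    dist = squareform(pdist(pooled, metric="hamming")) * pooled.shape[1]
    mds = MDS(
        n_components=2, metric_mds=False, metric="precomputed",
        normalized_stress=True, n_init=4, max_iter=max_iter, init="random",
        random_state=int(rng.integers(2**31 - 1)), eps=1e-6,
    )
    coords = mds.fit_transform(dist)
    labels = np.repeat(["spontaneous", "shuffled", "evoked"], n_points)
    converged = mds.n_iter_ < max_iter
    if not converged:
        warnings.warn("MDS did not converge; returning the best embedding found")
    return MdsEmbedding(coordinates=coords, labels=labels,
                        stress=float(mds.stress_), converged=converged)


def nearest_state_distances(
    evoked: np.ndarray, spontaneous: np.ndarray, shuffled: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hamming distance from each evoked state to its nearest neighbour in
    the spontaneous set (D_spont) and in the shuffled set (D_shuff)."""
    for arr in (evoked, spontaneous, shuffled):
        if np.asarray(arr).shape[0] == 0:
            raise ValueError("state sets must be nonempty")
    n = np.asarray(evoked).shape[1]
    d_spont = cdist(evoked, spontaneous, metric="hamming").min(axis=1) * n
    d_shuff = cdist(evoked, shuffled, metric="hamming").min(axis=1) * n
    return d_spont, d_shuff


# ---------------------------------------------------------------------------
# KL divergence of pattern distributions
# ---------------------------------------------------------------------------

def _pattern_keys(spikes: np.ndarray, units: np.ndarray) -> np.ndarray:
    bits = spikes[:, units].astype(np.int64)
    powers = 1 << np.arange(units.size, dtype=np.int64)
    return bits @ powers


def kl_evoked_vs_spontaneous(
    evoked_spikes: np.ndarray,
    spont_spikes: np.ndarray,
    n_units: int = 16,
    rng: Optional[np.random.Generator] = None,
    exclude_initial: int = 5000,
    units: Optional[np.ndarray] = None,
) -> float:
    """KL(P_evoked || P_spont) over binary patterns of a random unit subsample.

    Pattern probabilities use an add-one prior (every one of the ``2**k``
    patterns counts as observed once), so the divergence is finite; patterns
    observed in neither recording contribute through a closed form rather
    than by enumeration.  Both recordings must have equal length and the
    first ``exclude_initial`` steps of each are discarded (threshold
    re-adaptation after a paradigm change).
    """
    if n_units > 24:
        raise ValueError("n_units > 24 refused (pattern space too large)")
    if evoked_spikes.shape[0] != spont_spikes.shape[0]:
        raise ValueError("recordings must have equal length")
    ev = evoked_spikes[exclude_initial:]
    sp = spont_spikes[exclude_initial:]
    if units is None:
        if rng is None:
            rng = np.random.default_rng()
        units = rng.choice(evoked_spikes.shape[1], size=n_units, replace=False)
    units = np.asarray(units)

    n_patterns = 1 << units.size
    t = ev.shape[0]
    z_e = t + n_patterns
    z_s = t + n_patterns

    keys_e = _pattern_keys(ev, units)
    keys_s = _pattern_keys(sp, units)
    uniq_e, cnt_e = np.unique(keys_e, return_counts=True)
    uniq_s, cnt_s = np.unique(keys_s, return_counts=True)
    union = np.union1d(uniq_e, uniq_s)

    def counts_on(union_keys, uniq, cnt):
        out = np.zeros(union_keys.size, dtype=np.int64)
        pos = np.searchsorted(uniq, union_keys)
        ok = (pos < uniq.size)
        ok[ok] &= uniq[pos[ok]] == union_keys[ok]
        out[ok] = cnt[pos[ok]]
        return out

    ce = counts_on(union, uniq_e, cnt_e) + 1
    cs = counts_on(union, uniq_s, cnt_s) + 1
    pe = ce / z_e
    ps = cs / z_s
    kl = float(np.sum(pe * np.log(pe / ps)))
    # patterns unseen in both recordings (count 1 in each after the prior)
    n_unseen = n_patterns - union.size
    kl += n_unseen * (1.0 / z_e) * np.log((1.0 / z_e) / (1.0 / z_s))
    return kl


# ---------------------------------------------------------------------------
# pattern decoding and transitions
# ---------------------------------------------------------------------------

def build_pattern_dictionary(
    evoked_states: np.ndarray,
    letters: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> PatternDictionary:
    """Balanced evoked dictionary: blanks excluded, letters equally frequent.

    Entries are ordered by letter (alphabetical) and, within a letter, by
    their position in the recording, which makes the nearest-neighbour
    tie-break (smallest letter index, then earliest entry) a plain argmin.
    """
    letters = np.asarray(letters)
    keep = letters != BLANK
    states, letters = np.asarray(evoked_states)[keep], letters[keep]
    if states.shape[0] == 0:
        raise ValueError("no evoked (non-blank) states supplied")
    alphabet = sorted(np.unique(letters))
    n = min((letters == c).sum() for c in alphabet)
    parts, labs = [], []
    for c in alphabet:
        idx = np.flatnonzero(letters == c)
        if rng is not None and idx.size > n:
            idx = np.sort(rng.choice(idx, size=n, replace=False))
        else:
            idx = idx[-n:]
        parts.append(states[idx])
        labs.append(np.full(n, c, dtype=letters.dtype))
    return PatternDictionary(
        evoked_states=np.vstack(parts), letters=np.concatenate(labs),
        alphabet=list(alphabet),
    )


def assign_letters(
    dictionary: PatternDictionary, spontaneous: np.ndarray, chunk: int = 512
) -> np.ndarray:
    """Label each spontaneous state with the letter of its nearest evoked state.

    Nearest is by Hamming distance; ties resolve to the smallest letter
    index and then the earliest dictionary entry (the dictionary ordering).
    """
    if dictionary.evoked_states.shape[0] == 0:
        raise ValueError("empty pattern dictionary")
    spont = np.asarray(spontaneous)
    out = np.empty(spont.shape[0], dtype=dictionary.letters.dtype)
    for s in range(0, spont.shape[0], chunk):
        d = cdist(spont[s : s + chunk], dictionary.evoked_states, metric="hamming")
        out[s : s + chunk] = dictionary.letters[np.argmin(d, axis=1)]
    return out


def word_letter_frequencies(
    labelled_states: np.ndarray, words: Sequence[str]
) -> tuple[dict, dict, bool]:
    """Letter and word frequencies decoded from a labelled state sequence.

    Word frequencies count occurrences of the given words *and their
    reversals* in the decoded letter string, normalized over the total count
    of those words.  Returns (letter_freq, word_freq, found_any); if no
    word occurs at all, the word table is all-zero and ``found_any`` False.
    """
    labels = np.asarray(labelled_states)
    letter_freq = {c: float((labels == c).mean()) for c in sorted(np.unique(labels))}
    stream = "".join(labels.tolist())
    word_set = list(words) + [w[::-1] for w in words]
    counts = {}
    for w in word_set:
        k = len(w)
        counts[w] = sum(
            1 for i in range(len(stream) - k + 1) if stream[i : i + k] == w
        )
    total = sum(counts.values())
    if total == 0:
        return letter_freq, {w: 0.0 for w in word_set}, False
    return letter_freq, {w: c / total for w, c in counts.items()}, True


def empirical_transitions(labelled_states: np.ndarray) -> TransitionMatrix:
    """First-order letter-transition probabilities of a labelled sequence."""
    labels = np.asarray(labelled_states)
    letters = sorted(np.unique(labels))
    index = {c: k for k, c in enumerate(letters)}
    counts = np.zeros((len(letters), len(letters)))
    a = np.fromiter((index[c] for c in labels), dtype=np.intp, count=labels.size)
    np.add.at(counts, (a[:-1], a[1:]), 1)
    probs = counts.copy()
    rows = counts.sum(axis=1)
    probs[rows > 0] /= rows[rows > 0, None]
    return TransitionMatrix(letters=list(letters), probabilities=probs, counts=counts)


def svd_transition_prediction(
    w_ee: np.ndarray,
    evoked_states: np.ndarray,
    letters: np.ndarray,
) -> TransitionMatrix:
    """Letter-transition structure predicted from the SVD of W_ee.

    Each singular triplet (u_i, sigma_i, v_i) describes a one-step linear
    transition v_i -> u_i; both vectors are matched to the letter of the
    evoked state with the maximal dot product, evaluating both sign
    orientations of the pair jointly and keeping the better one.  Singular
    values accumulate on the (letter(v) -> letter(u)) cell and rows are
    normalized to one.
    """
    w = np.asarray(w_ee, dtype=float)
    if not np.any(w):
        raise ValueError("zero weight matrix has no transition structure")
    letters = np.asarray(letters)
    keep = letters != BLANK
    states = np.asarray(evoked_states, dtype=float)[keep]
    labels = letters[keep]
    alphabet = sorted(np.unique(labels))
    index = {c: k for k, c in enumerate(alphabet)}

    u_mat, s, vt = np.linalg.svd(w)
    du = states @ u_mat                         # (M, N) dot products per component
    dv = states @ vt.T
    acc = np.zeros((len(alphabet), len(alphabet)))
    for i in range(s.size):
        if s[i] <= 0:
            continue
        plus = du[:, i].max() + dv[:, i].max()
        minus = (-du[:, i]).max() + (-dv[:, i]).max()
        if plus >= minus:
            lu = labels[np.argmax(du[:, i])]
            lv = labels[np.argmax(dv[:, i])]
        else:
            lu = labels[np.argmax(-du[:, i])]
            lv = labels[np.argmax(-dv[:, i])]
        acc[index[lv], index[lu]] += s[i]
    probs = acc.copy()
    rows = acc.sum(axis=1)
    probs[rows > 0] /= rows[rows > 0, None]
    return TransitionMatrix(letters=list(alphabet), probabilities=probs, counts=acc)
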