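"""Stimulation paradigms: symbolic streams, input maps and experiment presets.

Every experiment follows the same three-phase schedule:

1. *self-organization* (default 50000 steps): all plasticity rules active,
   the network adapts to the stimulus statistics;
2. *training* (20000 steps): STDP (and the normalization it drives) is off,
   IP stays on; evoked activity is recorded and readouts are trained;
3. *testing* (50000 steps): IP only; either spontaneous activity is observed
   (no input) or test stimuli are presented.

After each phase the excitatory state vector is shuffled across neurons.

Letters denote one-step input vectors; ``"_"`` is a blank (no input).  Each
letter stimulates a pool of ``n_input`` excitatory neurons with constant
weight ``w_in``.  Ambiguous cues mix the pools of two letters: a fraction
``f_a`` of the "A" pool plus the complementary fraction of the "B" pool,
redrawn on every trial.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import (
    PhaseProtocol,
    SornState,
    SpikeRecording,
    init_network,
    run_phase,
    spawn_rngs,
)
from .params import SornParams
from .readout import LinearReadout, decide, fit_decision_readout, parse_trials
from .stats import TrialTensor

__all__ = [
    "InputMap",
    "TaskSpec",
    "AmbiguousCue",
    "build_input_map",
    "sample_stimulus_stream",
    "compile_stream",
    "run_experiment",
    "run_random_letters",
    "run_sequence_recognition",
    "run_sequence_priors",
    "run_inference",
    "PRESETS",
]

BLANK = "_"


# ---------------------------------------------------------------------------
# input mapping
# ---------------------------------------------------------------------------

@dataclass
class InputMap:
    """Letter -> excitatory target-pool assignment."""

    alphabet: list
    pools: dict                      # letter -> np.ndarray of target indices
    n_input: int
    disjoint: tuple = ()

    def pool(self, letter: str) -> np.ndarray:
        return self.pools[letter]

    def input_units(self, letters: Optional[Sequence[str]] = None) -> np.ndarray:
        """Sorted union of pool indices for ``letters`` (default: all)."""
        letters = self.alphabet if letters is None else letters
        if not letters:
            return np.zeros(0, dtype=np.intp)
        return np.unique(np.concatenate([self.pools[c] for c in letters]))

    def w_eu(self, n_exc: int, w_in: float) -> np.ndarray:
        """Dense input weight matrix (n_exc x n_letters)."""
        w = np.zeros((n_exc, len(self.alphabet)))
        for k, letter in enumerate(self.alphabet):
            w[self.pools[letter], k] = w_in
        return w


def build_input_map(
    alphabet: Sequence[str],
    params: SornParams,
    disjoint_letters: Sequence[str] = (),
    rng: Optional[np.random.Generator] = None,
) -> InputMap:
    """Sample input pools; pools may overlap except between ``disjoint_letters``."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    alphabet = list(alphabet)
    disjoint = tuple(disjoint_letters)
    unknown = set(disjoint) - set(alphabet)
    if unknown:
        raise ValueError(f"disjoint letters {sorted(unknown)} not in alphabet")
    if params.n_input * len(disjoint) > params.n_exc:
        raise ValueError(
            f"cannot allocate {len(disjoint)} disjoint pools of "
            f"{params.n_input} units from {params.n_exc} excitatory neurons"
        )
    pools = {}
    if disjoint:
        joint = rng.choice(params.n_exc, size=params.n_input * len(disjoint), replace=False)
        for k, letter in enumerate(disjoint):
            pools[letter] = np.sort(joint[k * params.n_input : (k + 1) * params.n_input])
    for letter in alphabet:
        if letter not in pools:
            pools[letter] = np.sort(
                rng.choice(params.n_exc, size=params.n_input, replace=False)
            )
    return InputMap(alphabet=alphabet, pools=pools, n_input=params.n_input, disjoint=disjoint)


@dataclass
class AmbiguousCue:
    """One-trial mixture of two letter pools with ambiguity fraction ``f_a``."""

    f_a: float
    active_units: np.ndarray

    @classmethod
    def draw(
        cls,
        f_a: float,
        input_map: InputMap,
        rng: np.random.Generator,
        letter_a: str = "A",
        letter_b: str = "B",
    ) -> "AmbiguousCue":
        n = input_map.n_input
        k = f_a * n
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"f_a={f_a} is not a multiple of 1/{n}")
        k = int(round(k))
        a_units = rng.choice(input_map.pool(letter_a), size=k, replace=False)
        b_units = rng.choice(input_map.pool(letter_b), size=n - k, replace=False)
        return cls(f_a=f_a, active_units=np.concatenate([a_units, b_units]).astype(np.intp))


# ---------------------------------------------------------------------------
# symbolic streams
# ---------------------------------------------------------------------------

@dataclass
class TaskSpec:
    """Word inventory with priors and inter-word blank interval."""

    words: list
    priors: np.ndarray
    blank_interval: tuple = (0, 0)
    phase_lengths: tuple = (50_000, 20_000, 50_000)

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if len(self.words) != self.priors.size:
            raise ValueError("one prior per word required")
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        lo, hi = self.blank_interval
        if lo > hi or lo < 0:
            raise ValueError("blank interval must satisfy 0 <= lo <= hi")


def sample_stimulus_stream(
    spec: TaskSpec, length: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. word draws per prior, each followed by a uniform blank run.

    The stream is truncated to exactly ``length`` steps (a final word may be
    cut short).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    out: list = []
    total = 0
    lo, hi = spec.blank_interval
    while total < length:
        w = spec.words[rng.choice(len(spec.words), p=spec.priors)]
        out.extend(w)
        total += len(w)
        n_blank = int(rng.integers(lo, hi + 1)) if hi > 0 else lo
        if n_blank:
            out.extend(BLANK * n_blank)
            total += n_blank
    return np.array(out[:length], dtype="U8")


def compile_stream(
    letters: np.ndarray,
    input_map: InputMap,
    params: SornParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Translate a letter stream into (sym, drive) arrays for a protocol.

    Row 0 of the drive table is the blank; rows 1.. follow the alphabet.
    """
    drive = np.zeros((1 + len(input_map.alphabet), params.n_exc))
    index = {BLANK: 0}
    for k, letter in enumerate(input_map.alphabet):
        drive[1 + k, input_map.pool(letter)] = params.w_in
        index[letter] = 1 + k
    try:
        sym = np.array([index[c] for c in letters], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"letter {exc} not covered by the input map") from None
    return sym, drive


def _protocol(letters, input_map, params, *, plastic, name, **kw) -> PhaseProtocol:
    sym, drive = compile_stream(letters, input_map, params)
    return PhaseProtocol(
        sym=sym, drive=drive, letters=np.asarray(letters, dtype="U8"),
        stdp=plastic, sn=plastic, structural=plastic, ip=True, name=name, **kw,
    )


def _blank_letters(n: int) -> np.ndarray:
    return np.full(n, BLANK, dtype="U8")


# ---------------------------------------------------------------------------
# experiment presets
# ---------------------------------------------------------------------------

@dataclass
class RandomLettersResult:
    params: SornParams
    input_map: InputMap
    state: SornState
    w_ee: np.ndarray
    conn_fraction: np.ndarray
    connection_sample_every: int
    recordings: dict


def run_random_letters(
    params: Optional[SornParams] = None,
    seed: Optional[int] = None,
    n_letters: int = 10,
    t_plastic: int = 50_000,
    t_spontaneous: int = 50_000,
    conn_sample_every: int = 100,
) -> RandomLettersResult:
    """Random alternation of single letters, then spontaneous activity.

    Characterizes the basic network statistics: irregular Poisson-like
    spiking, convergent connection fraction and lognormal-like weights.
    """
    params = params if params is not None else SornParams(t_i_max=0.35)
    rngs = spawn_rngs(seed if seed is not None else params.seed,
                      ["init", "map", "stream", "phase"])
    alphabet = [chr(ord("A") + i) for i in range(n_letters)]
    imap = build_input_map(alphabet, params, rng=rngs["map"])
    state = init_network(params, rng=rngs["init"], w_eu=imap.w_eu(params.n_exc, params.w_in))

    letters = np.asarray(alphabet, dtype="U8")[
        rngs["stream"].integers(0, n_letters, size=t_plastic)
    ]
    proto = _protocol(letters, imap, params, plastic=True, name="self-organization",
                      connection_sample_every=conn_sample_every)
    state, rec_plastic = run_phase(state, proto, rngs["phase"])
    w_ee = state.w_ee.copy()

    proto_sp = _protocol(_blank_letters(t_spontaneous), imap, params, plastic=False,
                         name="spontaneous")
    state, rec_spont = run_phase(state, proto_sp, rngs["phase"])

    return RandomLettersResult(
        params=params, input_map=imap, state=state, w_ee=w_ee,
        conn_fraction=rec_plastic.connection_fraction,
        connection_sample_every=conn_sample_every,
        recordings={"self_organization": rec_plastic, "spontaneous": rec_spont},
    )


@dataclass
class SequenceRecognitionResult:
    params: SornParams
    input_map: InputMap
    trained: str
    magnitudes: dict                  # test word -> mean rate over word steps
    n_presentations: int


def _word_block(word: str, blank: int) -> list:
    return list(word) + [BLANK] * blank


def run_sequence_recognition(
    params: Optional[SornParams] = None,
    seed: Optional[int] = None,
    train: str = "ABCD",
    control_permutations: bool = False,
    test_words: Sequence[str] = ("ABCD", "DCBA", "A_CD", "E_CD"),
    t_plastic: int = 50_000,
    t_sleep: int = 20_000,
    n_test_presentations: int = 25,
    blank: int = 10,
) -> SequenceRecognitionResult:
    """Sequence-learning paradigm: train on a word, test recognition.

    Training presents either the single word or (control) all its
    permutations with equal probability, each followed by a fixed 10-step
    blank.  A stimulus-free "sleep" period follows, then each test word is
    presented from a copy of the same post-sleep state and the "sequence
    magnitude" (mean excitatory population rate over the word steps) is
    measured.

    The test probe is deliberately brief (default 25 presentations): the
    intrinsic plasticity that stays on during testing drives every neuron
    back to its target rate on a timescale of ~1/eta_ip steps, so a probe
    long compared to that measures the homeostatic equilibrium (identical
    rates for any stimulus) rather than the learned transient response.
    """
    params = params if params is not None else SornParams(t_i_max=0.35)
    rngs = spawn_rngs(seed if seed is not None else params.seed,
                      ["init", "map", "stream", "phase"])
    alphabet = sorted({c for w in list(test_words) + [train] for c in w if c != BLANK})
    imap = build_input_map(alphabet, params, rng=rngs["map"])
    state = init_network(params, rng=rngs["init"], w_eu=imap.w_eu(params.n_exc, params.w_in))

    if control_permutations:
        words = ["".join(p) for p in itertools.permutations(train)]
    else:
        words = [train]
    spec = TaskSpec(words=words, priors=np.full(len(words), 1.0 / len(words)),
                    blank_interval=(blank, blank))
    letters = sample_stimulus_stream(spec, t_plastic, rngs["stream"])
    state, _ = run_phase(
        state, _protocol(letters, imap, params, plastic=True, name="self-organization"),
        rngs["phase"],
    )
    state, _ = run_phase(
        state, _protocol(_blank_letters(t_sleep), imap, params, plastic=False, name="sleep"),
        rngs["phase"],
    )

    word_len = len(train)
    magnitudes = {}
    for tw in test_words:
        test_state = state.copy()
        block = _word_block(tw, blank)
        letters_t = np.array(block * n_test_presentations, dtype="U8")
        proto = _protocol(letters_t, imap, params, plastic=False, name=f"test-{tw}")
        _, rec = run_phase(test_state, proto, rngs["phase"])
        onsets = np.arange(n_test_presentations) * len(block)
        word_steps = (onsets[:, None] + np.arange(word_len)[None, :]).ravel()
        magnitudes[tw] = float(rec.spikes[word_steps].mean())

    return SequenceRecognitionResult(
        params=params, input_map=imap,
        trained="permutations" if control_permutations else train,
        magnitudes=magnitudes, n_presentations=n_test_presentations,
    )


@dataclass
class TwoWordResult:
    params: SornParams
    input_map: InputMap
    spec: TaskSpec
    state: SornState
    w_ee: np.ndarray                  # frozen after self-organization
    recordings: dict                  # training / spontaneous (and optional controls)


def run_sequence_priors(
    params: Optional[SornParams] = None,
    seed: Optional[int] = None,
    words: Sequence[str] = ("ABCD", "EFGH"),
    priors: Sequence[float] = (2 / 3, 1 / 3),
    phase_lengths: tuple = (50_000, 20_000, 50_000),
    evoked_control_words: Optional[Sequence[str]] = None,
    t_evoked_control: Optional[int] = None,
    keep_plastic_recording: bool = False,
) -> TwoWordResult:
    """Two-word task: continuous stimulation with word priors.

    Self-organize on randomly interleaved words, record evoked activity with
    STDP off (training phase), then observe spontaneous activity (testing
    phase).  If ``evoked_control_words`` is given, additional evoked phases
    (natural word set and the control set) are run from copies of the
    post-training state for KL comparisons.
    """
    params = params if params is not None else SornParams(t_i_max=0.35)
    rngs = spawn_rngs(seed if seed is not None else params.seed,
                      ["init", "map", "stream", "phase", "control"])
    t_plastic, t_train, t_test = phase_lengths
    alphabet = sorted({c for w in words for c in w})
    if evoked_control_words:
        alphabet = sorted(set(alphabet) | {c for w in evoked_control_words for c in w})
    imap = build_input_map(alphabet, params, rng=rngs["map"])
    state = init_network(params, rng=rngs["init"], w_eu=imap.w_eu(params.n_exc, params.w_in))

    spec = TaskSpec(words=list(words), priors=np.asarray(priors),
                    blank_interval=(0, 0), phase_lengths=phase_lengths)
    recordings = {}

    letters = sample_stimulus_stream(spec, t_plastic, rngs["stream"])
    state, rec = run_phase(
        state, _protocol(letters, imap, params, plastic=True, name="self-organization"),
        rngs["phase"],
    )
    if keep_plastic_recording:
        recordings["self_organization"] = rec
    w_ee = state.w_ee.copy()

    letters = sample_stimulus_stream(spec, t_train, rngs["stream"])
    state, recordings["training"] = run_phase(
        state, _protocol(letters, imap, params, plastic=False, name="training"),
        rngs["phase"],
    )

    if evoked_control_words is not None:
        n_ctrl = t_evoked_control if t_evoked_control is not None else t_train
        for label, wset in (("evoked_natural", list(words)),
                            ("evoked_control", list(evoked_control_words))):
            cspec = TaskSpec(words=wset, priors=np.full(len(wset), 1.0 / len(wset)),
                             blank_interval=(0, 0))
            cletters = sample_stimulus_stream(cspec, n_ctrl, rngs["control"])
            cstate = state.copy()
            _, recordings[label] = run_phase(
                cstate, _protocol(cletters, imap, params, plastic=False, name=label),
                rngs["control"],
            )

    state, recordings["spontaneous"] = run_phase(
        state,
        _protocol(_blank_letters(t_test), imap, params, plastic=False, name="spontaneous"),
        rngs["phase"],
    )
    return TwoWordResult(params=params, input_map=imap, spec=spec, state=state,
                         w_ee=w_ee, recordings=recordings)


# ---------------------------------------------------------------------------
# inference task
# ---------------------------------------------------------------------------

@dataclass
class InferenceResult:
    params: SornParams
    input_map: InputMap
    prior_a: float
    condition: str                    # "full" or "ip_only"
    test_mode: str                    # "ambiguous" or "unambiguous"
    readout: LinearReadout
    decisions: pd.DataFrame           # trial, onset, f_a, cue, decision
    curve: pd.DataFrame               # f_a, fraction_a, n_trials
    trials: TrialTensor
    recordings: dict

    def decision_curve(self) -> pd.DataFrame:
        return self.curve


def _inference_stream(
    input_map: InputMap,
    params: SornParams,
    prior_a: float,
    length: int,
    rng: np.random.Generator,
    mask: str = "XXX",
    blank_interval: tuple = (10, 15),
    f_grid: Optional[np.ndarray] = None,
):
    """Trial stream 'AXXX___…'/'BXXX___…' (or ambiguous 'A/B' cues).

    Returns (letters, sym, drive, trials) where ``trials`` records the cue
    onset, the decision step (first blank after the mask) and the cue
    composition of every complete trial.
    """
    base_sym, base_drive = compile_stream(
        np.array(list("AB") + list(mask[:1]), dtype="U8"), input_map, params
    )
    del base_sym
    row = {BLANK: 0}
    for k, letter in enumerate(input_map.alphabet):
        row[letter] = 1 + k

    letters: list = []
    sym: list = []
    extra_rows: list = []
    trials: list = []
    lo, hi = blank_interval
    mask_rows = [row[c] for c in mask]
    while len(sym) < length:
        onset = len(sym)
        if f_grid is None:
            cue_letter = "A" if rng.random() < prior_a else "B"
            f_a = 1.0 if cue_letter == "A" else 0.0
            letters.append(cue_letter)
            sym.append(row[cue_letter])
        else:
            f_a = float(f_grid[rng.integers(len(f_grid))])
            cue = AmbiguousCue.draw(f_a, input_map, rng)
            dr = np.zeros(params.n_exc)
            dr[cue.active_units] = params.w_in
            extra_rows.append(dr)
            cue_letter = "A/B"
            letters.append(cue_letter)
            sym.append(base_drive.shape[0] + len(extra_rows) - 1)
        for c, r in zip(mask, mask_rows):
            letters.append(c)
            sym.append(r)
        decision_step = onset + 1 + len(mask)
        n_blank = int(rng.integers(lo, hi + 1))
        letters.extend(BLANK * n_blank)
        sym.extend([0] * n_blank)
        if decision_step < length:
            trials.append((onset, decision_step, f_a, cue_letter))

    letters = np.array(letters[:length], dtype="U8")
    sym = np.array(sym[:length], dtype=np.int64)
    drive = base_drive if not extra_rows else np.vstack([base_drive] + extra_rows)
    trials = pd.DataFrame(trials, columns=["onset", "decision_step", "f_a", "cue"])
    return letters, sym, drive, trials


def run_inference(
    params: Optional[SornParams] = None,
    seed: Optional[int] = None,
    prior_a: float = 0.33,
    phase_lengths: tuple = (50_000, 20_000, 50_000),
    plasticity: str = "full",
    test_mode: str = "ambiguous",
    f_grid: Optional[np.ndarray] = None,
    mask: str = "XXX",
    blank_interval: tuple = (10, 15),
    trial_window: tuple = (10, 12),
    keep_recordings: bool = True,
) -> InferenceResult:
    """Ambiguous-cue inference task with a linear decision readout.

    The network self-organizes on randomly alternating trials
    ``AXXX___…`` (probability ``prior_a``) and ``BXXX___…``; the cue pools of
    "A" and "B" are disjoint.  With STDP off, a least-squares readout is
    trained to postdict the cue from the state at the first blank after the
    mask.  During testing, ambiguous mixtures of the two cue pools are
    presented (fractions ``f_grid``) and the readout decision is recorded
    per trial, yielding the decision curve over the ambiguity fraction.

    ``plasticity="ip_only"`` disables STDP/SN/structural plasticity during
    self-organization (IP stays on); ``test_mode="unambiguous"`` presents
    plain "A"/"B" trials at the training prior instead of the ambiguity grid
    (used for the trial-aligned variability analyses).
    """
    if plasticity not in ("full", "ip_only"):
        raise ValueError("plasticity must be 'full' or 'ip_only'")
    if test_mode not in ("ambiguous", "unambiguous"):
        raise ValueError("test_mode must be 'ambiguous' or 'unambiguous'")
    params = params if params is not None else SornParams(t_i_max=1.0)
    if f_grid is None:
        f_grid = np.round(np.arange(0, 11) / 10, 1)
    rngs = spawn_rngs(seed if seed is not None else params.seed,
                      ["init", "map", "stream", "cues", "phase"])
    t_plastic, t_train, t_test = phase_lengths

    imap = build_input_map(list("AB") + sorted(set(mask)), params,
                           disjoint_letters=("A", "B"), rng=rngs["map"])
    state = init_network(params, rng=rngs["init"], w_eu=imap.w_eu(params.n_exc, params.w_in))
    recordings: dict = {}

    # self-organization
    letters, sym, drive, _ = _inference_stream(
        imap, params, prior_a, t_plastic, rngs["stream"], mask, blank_interval
    )
    plastic = plasticity == "full"
    proto = PhaseProtocol(sym=sym, drive=drive, letters=letters, stdp=plastic,
                          sn=plastic, structural=plastic, ip=True,
                          name="self-organization")
    state, rec = run_phase(state, proto, rngs["phase"])
    if keep_recordings:
        recordings["self_organization"] = rec

    # training (STDP off) and readout fit
    letters, sym, drive, train_trials = _inference_stream(
        imap, params, prior_a, t_train, rngs["stream"], mask, blank_interval
    )
    proto = PhaseProtocol(sym=sym, drive=drive, letters=letters, stdp=False,
                          sn=False, structural=False, ip=True, name="training")
    state, rec_train = run_phase(state, proto, rngs["phase"])
    readout = fit_decision_readout(rec_train, mask_len=len(mask), rng=rngs["cues"])
    if keep_recordings:
        recordings["training"] = rec_train

    # testing
    letters, sym, drive, test_trials = _inference_stream(
        imap, params, prior_a, t_test, rngs["stream"], mask, blank_interval,
        f_grid=f_grid if test_mode == "ambiguous" else None,
    )
    proto = PhaseProtocol(sym=sym, drive=drive, letters=letters, stdp=False,
                          sn=False, structural=False, ip=True, name="testing")
    state, rec_test = run_phase(state, proto, rngs["phase"])
    if keep_recordings:
        recordings["testing"] = rec_test

    dec_states = rec_test.spikes[test_trials["decision_step"].to_numpy()]
    test_trials = test_trials.copy()
    test_trials["decision"] = [decide(readout, s) for s in dec_states]

    if test_mode == "ambiguous":
        grp = test_trials.groupby("f_a")["decision"]
        curve = pd.DataFrame({
            "f_a": grp.size().index.to_numpy(),
            "fraction_a": grp.apply(lambda d: float((d == "A").mean())).to_numpy(),
            "n_trials": grp.size().to_numpy(),
        })
    else:
        grp = test_trials.groupby("cue")["decision"]
        curve = pd.DataFrame({
            "f_a": [1.0 if c == "A" else 0.0 for c in grp.size().index],
            "fraction_a": grp.apply(lambda d: float((d == "A").mean())).to_numpy(),
            "n_trials": grp.size().to_numpy(),
        })

    pre, post = trial_window
    conditions = (test_trials["f_a"] if test_mode == "ambiguous"
                  else test_trials["cue"]).to_numpy()
    tensor = TrialTensor.from_recording(
        rec_test, onsets=test_trials["onset"].to_numpy(), pre=pre, post=post,
        conditions=conditions, input_units=imap.input_units(),
    )
    test_trials = test_trials.loc[tensor.kept_trials].reset_index(drop=True)
    conditions = conditions[tensor.kept_trials]

    return InferenceResult(
        params=params, input_map=imap, prior_a=prior_a, condition=plasticity,
        test_mode=test_mode, readout=readout, decisions=test_trials, curve=curve,
        trials=tensor, recordings=recordings,
    )


PRESETS = {
    "random_letters": run_random_letters,
    "sequence_recognition": run_sequence_recognition,
    "sequence_priors": run_sequence_priors,
    "inference": run_inference,
}


def run_experiment(preset: str, params: Optional[SornParams] = None,
                   seed: Optional[int] = None, **kwargs):
    """Dispatch to one of the four experiment presets."""
    try:
        fn = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return fn(params=params, seed=seed, **kwargs)
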