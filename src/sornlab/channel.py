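"""Noisy-channel Naive Bayes reference model for the inference task.

Each of the 10 input units per cue population is a binary channel: a
stimulated unit is received correctly with probability ``theta1``, an
unstimulated one with probability ``theta0``.  A Naive Bayes classifier over
the 20 channel outputs, with prior p(A), defines the posterior p(A | n_a,
n_b) given the active-evidence counts of the two populations; stimulating a
fraction ``f_a`` of the "A" pool makes the counts binomial convolutions, and
averaging the posterior over them yields the exact decision curve
p(A | f_a).

Fitting the two channel parameters to measured network decision curves is
an exhaustive grid search over theta in {0.05, ..., 0.95}^2 minimizing the
summed mean squared deviation across priors, exposed both as the plain
function :func:`fit_channel_params` and as the model/results pair
:class:`NoisyChannelModel` / :class:`NoisyChannelFitResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import binom

__all__ = [
    "ChannelParams",
    "PosteriorCurve",
    "posterior_given_counts",
    "count_distribution",
    "posterior_curve",
    "fit_channel_params",
    "NoisyChannelModel",
    "NoisyChannelFitResults",
    "DEFAULT_F_GRID",
    "THETA_GRID",
]

DEFAULT_F_GRID = np.round(np.arange(11) / 10, 1)
THETA_GRID = np.round(np.arange(1, 20) * 0.05, 2)


@dataclass(frozen=True)
class ChannelParams:
    """Channel reliabilities, pool size and stimulus prior."""

    theta1: float                     # p(receive 1 | stimulated)
    theta0: float                     # p(receive 0 | not stimulated)
    n_units: int = 10
    prior_a: float = 0.5

    def __post_init__(self) -> None:
        for name in ("theta1", "theta0", "prior_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")


@dataclass
class PosteriorCurve:
    """Exact posterior p(A | f_a) on the ambiguity grid."""

    f_grid: np.ndarray
    p_a: np.ndarray
    neutral_f: float                  # f_a where p(A | f_a) crosses 0.5
    neutral_at_boundary: bool = False

    def p_b(self) -> np.ndarray:
        return 1.0 - self.p_a


def _log_likelihoods(ch: ChannelParams, n_a, n_b):
    n = ch.n_units
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    ll_a = (
        xlogy(n_a, ch.theta1) + xlogy(n - n_a, 1 - ch.theta1)
        + xlogy(n_b, 1 - ch.theta0) + xlogy(n - n_b, ch.theta0)
    )
    ll_b = (
        xlogy(n_a, 1 - ch.theta0) + xlogy(n - n_a, ch.theta0)
        + xlogy(n_b, ch.theta1) + xlogy(n - n_b, 1 - ch.theta1)
    )
    return ll_a, ll_b


def posterior_given_counts(ch: ChannelParams, n_a, n_b):
    """p(A | n_a, n_b): Bayes rule over the two training cases, in log space.

    ``n_a``/``n_b`` are the active-evidence counts of the two populations
    (scalars or arrays, each in 0..n_units).  If the evidence is impossible
    under both hypotheses the prior is returned.
    """
    n_a = np.asarray(n_a)
    n_b = np.asarray(n_b)
    if ((n_a < 0) | (n_a > ch.n_units) | (n_b < 0) | (n_b > ch.n_units)).any():
        raise ValueError(f"counts must lie in 0..{ch.n_units}")
    ll_a, ll_b = _log_likelihoods(ch, n_a, n_b)
    la = ll_a + np.log(ch.prior_a) if ch.prior_a > 0 else np.full_like(ll_a, -np.inf)
    lb = ll_b + np.log(1 - ch.prior_a) if ch.prior_a < 1 else np.full_like(ll_b, -np.inf)
    with np.errstate(invalid="ignore", over="ignore"):
        out = np.where(
            np.isneginf(la) & np.isneginf(lb),
            ch.prior_a,
            1.0 / (1.0 + np.exp(np.clip(lb - la, -745, 745))),
        )
    return float(out) if out.ndim == 0 else out


def count_distribution(ch: ChannelParams, f_a: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmfs of (n_a, n_b) for ambiguity fraction ``f_a``.

    n_a is the convolution of Binomial(f_a * n, theta1) (stimulated part of
    the A pool) and Binomial((1 - f_a) * n, 1 - theta0) (spontaneous noise in
    its unstimulated part); n_b swaps the roles.  ``f_a`` must be a grid
    multiple of 1/n (refused otherwise, not rounded).
    """
    n = ch.n_units
    k = f_a * n
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"f_a={f_a} is not a multiple of 1/{n}")
    k = int(round(k))

    def conv(n_stim, n_silent):
        p1 = binom.pmf(np.arange(n_stim + 1), n_stim, ch.theta1)
        p0 = binom.pmf(np.arange(n_silent + 1), n_silent, 1 - ch.theta0)
        return np.convolve(p1, p0)

    return conv(k, n - k), conv(n - k, k)


def posterior_curve(ch: ChannelParams, f_grid: Optional[np.ndarray] = None) -> PosteriorCurve:
    """Exact p(A | f_a) by enumerating the (n_units+1)^2 count pairs."""
    if f_grid is None:
        f_grid = DEFAULT_F_GRID
    f_grid = np.asarray(f_grid, dtype=float)
    counts = np.arange(ch.n_units + 1)
    post = posterior_given_counts(ch, counts[:, None], counts[None, :])
    p_a = np.empty(f_grid.size)
    for k, f in enumerate(f_grid):
        pa, pb = count_distribution(ch, f)
        p_a[k] = float(pa @ post @ pb)

    diff = p_a - 0.5
    neutral, at_boundary = None, False
    for k in range(f_grid.size - 1):
        if diff[k] == 0.0:
            neutral = float(f_grid[k])
            break
        if diff[k] * diff[k + 1] < 0:
            neutral = float(
                f_grid[k] + (f_grid[k + 1] - f_grid[k]) * (-diff[k]) / (diff[k + 1] - diff[k])
            )
            break
    if neutral is None:
        if diff[-1] == 0.0:
            neutral = float(f_grid[-1])
        else:
            neutral = float(f_grid[0] if diff[0] > 0 else f_grid[-1])
            at_boundary = True
    return PosteriorCurve(f_grid=f_grid, p_a=p_a, neutral_f=neutral,
                          neutral_at_boundary=at_boundary)


# ---------------------------------------------------------------------------
# grid-search fit to network decision curves
# ---------------------------------------------------------------------------

def fit_channel_params(
    decision_curves: Mapping[float, np.ndarray],
    n_units: int = 10,
    f_grid: Optional[np.ndarray] = None,
    theta_grid: Optional[np.ndarray] = None,
) -> tuple[ChannelParams, float, np.ndarray]:
    """Exhaustive grid search of (theta1, theta0) against measured curves.

    ``decision_curves`` maps each training prior p(A) to the measured
    fraction of "A"-decisions over the ambiguity grid.  The score of a
    parameter pair is the sum over priors of the mean squared deviation
    between the model posterior curve and the measurement; ties resolve to
    the larger theta1, then the larger theta0.  Returns the best parameters
    (``prior_a`` unset, 0.5), the minimal error and the full error grid.
    """
    if not decision_curves:
        raise ValueError("no decision curves supplied")
    if f_grid is None:
        f_grid = DEFAULT_F_GRID
    if theta_grid is None:
        theta_grid = THETA_GRID
    priors = sorted(decision_curves)
    measured = np.vstack([np.asarray(decision_curves[p], dtype=float) for p in priors])
    if measured.shape[1] != f_grid.size:
        raise ValueError("curve length does not match the ambiguity grid")

    errs = np.full((theta_grid.size, theta_grid.size), np.inf)
    counts = np.arange(n_units + 1)
    for i, t1 in enumerate(theta_grid):
        for j, t0 in enumerate(theta_grid):
            ch = ChannelParams(theta1=t1, theta0=t0, n_units=n_units)
            # count pmfs depend on (theta1, theta0, f) only; share them
            # across priors and shift the posterior by the log prior odds
            ll_a, ll_b = _log_likelihoods(ch, counts[:, None], counts[None, :])
            delta = ll_a - ll_b
            pmfs = [count_distribution(ch, f) for f in f_grid]
            total = 0.0
            for k, prior in enumerate(priors):
                odds = np.log(prior) - np.log1p(-prior)
                post = 1.0 / (1.0 + np.exp(np.clip(-(delta + odds), -745, 745)))
                model = np.array([pa @ post @ pb for pa, pb in pmfs])
                total += float(np.mean((model - measured[k]) ** 2))
            errs[i, j] = total
    best = np.min(errs)
    # Ties resolve toward larger theta1 then larger theta0.  The posterior
    # curve is exactly invariant under the evidence bit-flip
    # (theta1, theta0) -> (1 - theta1, 1 - theta0) and under the
    # stimulated/unstimulated role swap (theta1, theta0) -> (theta0, theta1),
    # so every minimum belongs to a four-fold symmetry class; the tolerance
    # absorbs float noise between the twins and the tie-break picks the
    # informative (large-theta1) representative.
    cands = np.argwhere(errs <= best * (1 + 1e-6) + 1e-12)
    i, j = max(cands, key=lambda ij: (theta_grid[ij[0]], theta_grid[ij[1]]))
    params = ChannelParams(theta1=float(theta_grid[i]), theta0=float(theta_grid[j]),
                           n_units=n_units)
    return params, float(errs[i, j]), errs


@dataclass
class NoisyChannelFitResults:
    """Grid-search fit of the noisy-channel model to decision curves."""

    model: "NoisyChannelModel"
    params: ChannelParams
    mse: float
    error_grid: np.ndarray
    theta_grid: np.ndarray

    @property
    def theta1(self) -> float:
        return self.params.theta1

    @property
    def theta0(self) -> float:
        return self.params.theta0

    def predicted_curve(self, prior_a: float) -> PosteriorCurve:
        ch = replace(self.params, prior_a=prior_a)
        return posterior_curve(ch, self.model.f_grid)

    def neutral_fractions(self) -> pd.DataFrame:
        rows = [(p, self.predicted_curve(p).neutral_f) for p in self.model.priors]
        return pd.DataFrame(rows, columns=["prior_a", "neutral_f"])

    def summary(self) -> str:
        lines = [
            "Noisy-channel Naive Bayes fit",
            "=============================",
            f"curves (priors):   {', '.join(f'{p:g}' for p in self.model.priors)}",
            f"ambiguity grid:    {self.model.f_grid[0]:g}..{self.model.f_grid[-1]:g} "
            f"({self.model.f_grid.size} points)",
            f"theta grid:        {self.theta_grid[0]:g}..{self.theta_grid[-1]:g} "
            f"step {self.theta_grid[1] - self.theta_grid[0]:g}",
            f"theta1 (stimulus transmission):      {self.theta1:.2f}",
            f"theta0 (non-stimulus transmission):  {self.theta0:.2f}",
            f"summed mean squared deviation:       {self.mse:.5f}",
        ]
        return "\n".join(lines)


class NoisyChannelModel:
    """Noisy-channel model bound to measured decision curves.

    Accepts either a tidy DataFrame with columns (prior, f_a, fraction_a) or
    a mapping {prior: curve over the ambiguity grid}; ``fit()`` runs the
    grid search and returns a :class:`NoisyChannelFitResults`.
    """

    def __init__(self, decision_curves, n_units: int = 10,
                 f_grid: Optional[np.ndarray] = None):
        self.f_grid = DEFAULT_F_GRID if f_grid is None else np.asarray(f_grid, float)
        self.n_units = n_units
        if isinstance(decision_curves, pd.DataFrame):
            curves = {}
            for prior, grp in decision_curves.groupby("prior"):
                grp = grp.sort_values("f_a")
                if not np.allclose(grp["f_a"].to_numpy(), self.f_grid):
                    raise ValueError(f"curve for prior {prior} does not cover the grid")
                curves[float(prior)] = grp["fraction_a"].to_numpy()
            self.curves = curves
        else:
            self.curves = {float(p): np.asarray(c, float)
                           for p, c in decision_curves.items()}
        if not self.curves:
            raise ValueError("no decision curves supplied")
        self.priors = sorted(self.curves)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "NoisyChannelModel":
        return cls(df, **kw)

    def fit(self, theta_grid: Optional[np.ndarray] = None) -> NoisyChannelFitResults:
        grid = THETA_GRID if theta_grid is None else np.asarray(theta_grid, float)
        params, mse, errs = fit_channel_params(
            self.curves, n_units=self.n_units, f_grid=self.f_grid, theta_grid=grid
        )
        return NoisyChannelFitResults(model=self, params=params, mse=mse,
                                      error_grid=errs, theta_grid=grid)
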