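"""State-based Markov-chain synchrony statistic.

Each annual series ``x_1..x_k`` is mapped to a state sequence ``Y_t`` on the
interior points ``t = 2..k-1``:

    state 1 (trough)    x_{t-1} >  x_t <= x_{t+1}
    state 2 (increase)  x_{t-1} <= x_t <= x_{t+1}
    state 3 (peak)      x_{t-1} <= x_t >  x_{t+1}
    state 4 (decrease)  x_{t-1} >  x_t >  x_{t+1}

The four conditions partition every real triplet, ties included.  Treating
``{Y_t}`` as a first-order Markov process with a shared 4x4 transition
matrix ``T``, the occupancy entropy at time t is

    H_t = -sum_j s_j(t) ln s_j(t)

where ``s_j(t)`` is the proportion of series in state j.  The synchrony
index compares H_t with its expectation under the null hypothesis that the
series are independent stationary chains driven by the same ``T``:

    phi_t = 1 - H_t / mean(H_null)

phi_t = 1 means perfect synchrony (all series in the same state); values
near 0 are consistent with independence; negative values indicate
systematic disagreement in excess of the null.  mean(H_null) is estimated
by Monte-Carlo simulation of independent chains started from the stationary
distribution of ``T``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    NonConvergenceError,
    SeriesTooShortError,
    UndefinedSynchronyError,
)

N_STATES = 4
LN_4 = float(np.log(N_STATES))


@dataclass(frozen=True)
class TransitionMatrix:
    """4x4 row-stochastic matrix of state-transition probabilities."""

    tau: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if tau.shape != (N_STATES, N_STATES) or np.any(tau < 0):
            raise ValueError("tau must be a nonnegative 4x4 matrix")
        if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every row of tau must sum to 1")


@dataclass(frozen=True)
class SynchronyResult:
    """Per-year entropy and synchrony index with its simulated null."""

    times: np.ndarray  # years t = 2..k-1
    state_a: np.ndarray
    state_b: np.ndarray
    H_t: np.ndarray
    phi_t: np.ndarray
    p_t: np.ndarray
    H_null_mean: float
    null_draws: np.ndarray  # all simulated step-level H values
    transition: TransitionMatrix
    n_sims: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.times,
                "H_t": self.H_t,
                "phi_t": self.phi_t,
                "p_t": self.p_t,
                "state_a": self.state_a,
                "state_b": self.state_b,
            }
        )

    def report(self, alpha: float = 0.05) -> dict:
        q05, q50, q95 = np.quantile(self.null_draws, [0.05, 0.5, 0.95])
        return {
            "n_sims": int(self.n_sims),
            "seed": int(self.seed),
            "H_null_mean": float(self.H_null_mean),
            "null_quantiles": {"q05": float(q05), "q50": float(q50), "q95": float(q95)},
            "years_synchronized": [
                int(y) for y, p in zip(self.times, self.phi_t) if abs(p - 1.0) < 1e-12
            ],
            "transition_matrix": np.asarray(self.transition.tau).tolist(),
        }

    def to_json(self, path, alpha: float = 0.05) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(alpha), fh, indent=2)


def classify_states(x) -> np.ndarray:
    """Map a series of k >= 3 values to its interior state sequence (length k-2)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise SeriesTooShortError(f"need at least 3 values, got {x.shape}")
    if np.any(~np.isfinite(x)):
        raise ValueError("series contains missing or non-finite values")
    prev, cur, nxt = x[:-2], x[1:-1], x[2:]
    states = np.empty(len(cur), dtype=int)
    states[(prev > cur) & (cur <= nxt)] = 1
    states[(prev <= cur) & (cur <= nxt)] = 2
    states[(prev <= cur) & (cur > nxt)] = 3
    states[(prev > cur) & (cur > nxt)] = 4
    return states


def estimate_transition_matrix(state_sequences) -> TransitionMatrix:
    """Estimate T from observed transitions pooled across sequences.

    Each row is normalized by its total; a state never observed as a
    transition origin gets the uniform row, so unobserved dynamics are
    neither forbidden nor biased toward any state.
    """
    seqs = [np.asarray(s, dtype=int) for s in state_sequences]
    if not seqs:
        raise ValueError("at least one state sequence is required")
    counts = np.zeros((N_STATES, N_STATES))
    for s in seqs:
        if np.any((s < 1) | (s > N_STATES)):
            raise ValueError("states must be in 1..4")
        np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1)
    row_tot = counts.sum(axis=1, keepdims=True)
    tau = np.where(row_tot > 0, counts / np.where(row_tot > 0, row_tot, 1), 1 / N_STATES)
    return TransitionMatrix(tau=tau, counts=counts)


def stationary_distribution(T: TransitionMatrix | np.ndarray, tol: float = 1e-10,
                            max_iter: int = 100_000) -> np.ndarray:
    """Stationary distribution s* with s*.T = s*, by power iteration.

    Starts from the uniform vector; for a non-ergodic matrix (e.g. the
    identity) this returns the uniform fixed point.
    """
    tau = T.tau if isinstance(T, TransitionMatrix) else np.asarray(T, dtype=float)
    s = np.full(N_STATES, 1 / N_STATES)
    for _ in range(max_iter):
        s_next = s @ tau
        s_next /= s_next.sum()
        if np.max(np.abs(s_next - s)) < tol:
            return s_next
        s = s_next
    raise NonConvergenceError(
        f"power iteration did not reach tol={tol}; residual "
        f"{np.max(np.abs(s @ tau - s)):.3e}"
    )


def occupancy(*states_at_t: int) -> np.ndarray:
    """Proportion of series in each of the 4 states at one time point."""
    s = np.bincount(np.asarray(states_at_t, dtype=int) - 1, minlength=N_STATES)
    return s / s.sum()


def entropy(s) -> float:
    """Shannon entropy -sum s ln s (nats), with 0 ln 0 := 0."""
    s = np.asarray(s, dtype=float)
    nz = s[s > 0]
    return float(-(nz * np.log(nz)).sum())


def _occupancy_entropy_rows(states: np.ndarray) -> np.ndarray:
    """Entropy of the occupancy vector for each row of an (m, n_series) array."""
    m, n_series = states.shape
    counts = np.zeros((m, N_STATES))
    rows = np.repeat(np.arange(m), n_series)
    np.add.at(counts, (rows, states.ravel() - 1), 1)
    p = counts / n_series
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


def simulate_null(
    T: TransitionMatrix | np.ndarray,
    length: int,
    n_sims: int,
    seed: int | np.random.Generator,
    n_series: int = 2,
    initial: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Monte-Carlo sample of occupancy entropies under independent chains.

    Simulates ``n_sims`` replicates of ``n_series`` independent chains of
    the given length from ``T``, each chain started from the stationary
    distribution of ``T`` (or from ``initial`` if given).  Returns the mean
    entropy over all replicates and time steps, and the full step-level
    sample of H values (shape ``n_sims * length``).
    """
    tau = T.tau if isinstance(T, TransitionMatrix) else np.asarray(T, dtype=float)
    if n_sims < 1 or length < 1:
        raise ValueError("n_sims and length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if initial is None:
        initial = stationary_distribution(tau)
    cum = np.cumsum(tau, axis=1)
    cum[:, -1] = 1.0  # guard rounding

    states = np.empty((n_sims, n_series, length), dtype=int)
    u0 = rng.random((n_sims, n_series))
    states[:, :, 0] = np.searchsorted(np.cumsum(initial), u0, side="right") + 1
    np.clip(states[:, :, 0], 1, N_STATES, out=states[:, :, 0])
    for t in range(1, length):
        u = rng.random((n_sims, n_series))
        prev = states[:, :, t - 1] - 1
        states[:, :, t] = (u[..., None] >= cum[prev]).sum(axis=-1) + 1

    H = _occupancy_entropy_rows(
        states.transpose(0, 2, 1).reshape(n_sims * length, n_series)
    )
    return float(H.mean()), H


def phi(H_t, H_null_mean: float):
    """Synchrony index phi = 1 - H_t / mean(H_null)."""
    if H_null_mean <= 0:
        raise UndefinedSynchronyError(
            "mean null entropy is not positive; phi is undefined (degenerate dynamics)"
        )
    return 1.0 - np.asarray(H_t, dtype=float) / H_null_mean


def synchrony_pvalue(H_t, null_sample) -> np.ndarray:
    """One-sided p-value toward synchrony (low entropy), add-one corrected.

    p = (1 + #{null H <= H_t}) / (1 + N).
    """
    null_sample = np.sort(np.asarray(null_sample, dtype=float))
    if null_sample.size == 0:
        raise ValueError("null sample is empty")
    H_t = np.asarray(H_t, dtype=float)
    r = np.searchsorted(null_sample, H_t, side="right")
    return (1.0 + r) / (1.0 + null_sample.size)


def run_synchrony(
    series_a,
    series_b,
    n_sims: int = 10_000,
    seed: int = 0,
    pool_transition: bool = True,
) -> SynchronyResult:
    """Full synchrony analysis of two aligned annual series.

    ``series_a``/``series_b`` are :class:`~eggsync.morphometrics.AnnualSeries`
    or plain arrays.  Both are state-classified; T is estimated from the two
    state sequences pooled (the shared-T assumption of the null); the null
    entropy distribution is simulated; per-year H_t, phi_t and p_t are
    returned.  Deterministic given ``seed``.
    """
    years_a = getattr(series_a, "years", None)
    x_a = np.asarray(getattr(series_a, "mean_volume_cm3", series_a), dtype=float)
    x_b = np.asarray(getattr(series_b, "mean_volume_cm3", series_b), dtype=float)
    if years_a is not None:
        years_b = getattr(series_b, "years", None)
        if years_b is not None and not np.array_equal(years_a, years_b):
            raise ValueError("the two series cover different year ranges")
        times = np.asarray(years_a[1:-1], dtype=int)
    else:
        times = np.arange(1, len(x_a) - 1)
    if len(x_a) != len(x_b):
        raise ValueError("series must have equal length")

    sa = classify_states(x_a)
    sb = classify_states(x_b)
    T = estimate_transition_matrix([sa, sb] if pool_transition else [sa])

    H_t = _occupancy_entropy_rows(np.column_stack([sa, sb]))
    H_null_mean, null_draws = simulate_null(T, length=len(sa), n_sims=n_sims, seed=seed)
    phi_t = phi(H_t, H_null_mean)
    p_t = synchrony_pvalue(H_t, null_draws)
    return SynchronyResult(
        times=times,
        state_a=sa,
        state_b=sb,
        H_t=H_t,
        phi_t=phi_t,
        p_t=p_t,
        H_null_mean=H_null_mean,
        null_draws=null_draws,
        transition=T,
        n_sims=n_sims,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
    )
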