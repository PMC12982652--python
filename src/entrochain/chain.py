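"""Exact quantities of two-time-scale Markov chains.

A *two-time-scale* chain models a patient's day-by-day trajectory as a Markov
chain over flattened (macro, micro) pairs: slow clinical macro-states (e.g.
acute, stable, prodromal regimes changing over weeks to months) each contain a
handful of fast daily micro-states (digitally observable behavioural symbols
such as regulated routine or fragmented activity).  Everything in this module
is analytic -- stationary distributions, entropy rates in bits/day, conditional
(macro-centric) entropy rates, mixing and mean recurrence times -- computed
from the transition matrix itself, with no simulation.

Conventions: logarithms are base 2, units are bits per day (one transition per
day), and 0 * log 0 = 0 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import (
    AllZeroRowError,
    DimensionMismatchError,
    MixingCapReachedError,
    NegativeEntryError,
    NonSquareMatrixError,
    ReducibleChainError,
)

_ATOL = 1e-9


@dataclass(frozen=True)
class StateSpace:
    """Bijection between (macro, micro) labels and 0-based flattened indices.

    Flattening is macro-major: all micro-states of the first macro come first,
    then the second macro's, and so on.  Micro label lists may be ragged.
    """

    macro_labels: tuple
    micro_labels_per_macro: tuple

    def __init__(self, macro_labels, micro_labels_per_macro):
        macro_labels = tuple(macro_labels)
        micro_labels_per_macro = tuple(tuple(m) for m in micro_labels_per_macro)
        if len(macro_labels) != len(set(macro_labels)):
            raise ValueError("duplicate macro labels")
        if len(macro_labels) != len(micro_labels_per_macro):
            raise ValueError("one micro-label list required per macro label")
        for macro, micros in zip(macro_labels, micro_labels_per_macro):
            if len(micros) != len(set(micros)):
                raise ValueError(f"duplicate micro labels under macro {macro!r}")
        object.__setattr__(self, "macro_labels", macro_labels)
        object.__setattr__(self, "micro_labels_per_macro", micro_labels_per_macro)

    @classmethod
    def uniform(cls, macro_labels, micro_labels):
        """Every macro-state carries the same micro alphabet."""
        macro_labels = tuple(macro_labels)
        return cls(macro_labels, (tuple(micro_labels),) * len(macro_labels))

    @property
    def n_macro(self) -> int:
        return len(self.macro_labels)

    @property
    def n_flat(self) -> int:
        return sum(len(m) for m in self.micro_labels_per_macro)

    @property
    def offsets(self):
        """Start index of each macro's block in the flattened ordering."""
        sizes = [len(m) for m in self.micro_labels_per_macro]
        return tuple(np.concatenate([[0], np.cumsum(sizes)[:-1]]).tolist())

    def block_slice(self, macro) -> slice:
        k = self.macro_labels.index(macro)
        start = self.offsets[k]
        return slice(start, start + len(self.micro_labels_per_macro[k]))

    def flat_index(self, macro, micro) -> int:
        k = self.macro_labels.index(macro)
        return self.offsets[k] + self.micro_labels_per_macro[k].index(micro)

    def unflatten(self, i: int):
        """Inverse of :meth:`flat_index`."""
        for k, macro in enumerate(self.macro_labels):
            micros = self.micro_labels_per_macro[k]
            if i < self.offsets[k] + len(micros):
                return macro, micros[i - self.offsets[k]]
        raise IndexError(i)

    @property
    def flat_labels(self):
        """Concatenated macro+micro labels, e.g. ('AR', 'AW', ..., 'EF')."""
        return tuple(
            f"{macro}{micro}"
            for macro, micros in zip(self.macro_labels, self.micro_labels_per_macro)
            for micro in micros
        )

    def macro_of_flat(self) -> np.ndarray:
        """Macro index of each flattened state."""
        out = np.empty(self.n_flat, dtype=int)
        for k in range(self.n_macro):
            s = self.block_slice(self.macro_labels[k])
            out[s] = k
        return out


@dataclass(frozen=True)
class TwoScaleChain:
    """A validated, row-stochastic daily transition matrix over flattened states.

    ``normalization_report`` records the row sums of the matrix as originally
    supplied, so any deviation from stochasticity in the source data remains
    auditable after normalization.
    """

    space: StateSpace
    P: np.ndarray
    normalization_report: dict = field(default_factory=dict)
    name: str = ""

    @property
    def n_states(self) -> int:
        return self.space.n_flat

    def block(self, macro) -> np.ndarray:
        """The raw (un-renormalized) within-macro block of P."""
        s = self.space.block_slice(macro)
        return self.P[s, s]

    def deviating_rows(self, tol: float = 0.01):
        """Flattened labels whose original row sum deviated from 1 by > tol."""
        return [
            lab
            for lab, s in self.normalization_report.items()
            if abs(s - 1.0) > tol
        ]


@dataclass(frozen=True)
class StationaryDistribution:
    """Probability vector aligned to a stated label set.

    ``level`` is one of ``"flat"``, ``"macro"`` or ``"micro"`` (the last for a
    single macro's conditional block).
    """

    values: np.ndarray
    labels: tuple
    level: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -_ATOL) or abs(v.sum() - 1.0) > 1e-8:
            raise ValueError("not a probability vector")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __getitem__(self, label):
        return float(self.values[self.labels.index(label)])

    def as_dict(self):
        return {lab: float(v) for lab, v in zip(self.labels, self.values)}


def validate_and_normalize(raw_matrix, space_or_labels, warn_tol=0.01, name=""):
    """Validate a nonnegative square matrix and row-normalize it to stochastic.

    Parameters
    ----------
    raw_matrix : array-like, shape (n, n)
        Nonnegative entries; rows need not sum to 1 (printed matrices often
        don't, to transcription precision or worse).
    space_or_labels : StateSpace or sequence of flattened labels
        Plain labels are wrapped in a degenerate one-macro StateSpace.
    warn_tol : float
        A ``UserWarning`` is emitted for every row whose original sum deviates
        from 1 by more than this fraction.

    Returns
    -------
    TwoScaleChain
        With each row divided by its sum and the original sums recorded in
        ``normalization_report``.
    """
    P = np.asarray(raw_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise NonSquareMatrixError(f"matrix has shape {P.shape}, expected square")
    if np.any(P < 0):
        i, j = np.argwhere(P < 0)[0]
        raise NegativeEntryError(f"negative entry {P[i, j]} at row {i}, column {j}")

    if isinstance(space_or_labels, StateSpace):
        space = space_or_labels
    else:
        labels = tuple(space_or_labels)
        space = StateSpace(("",), (labels,))
    if space.n_flat != P.shape[0]:
        raise DimensionMismatchError(
            f"{space.n_flat} labels for a {P.shape[0]}x{P.shape[0]} matrix"
        )

    sums = P.sum(axis=1)
    flat = space.flat_labels
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise AllZeroRowError(
            f"row(s) {[flat[i] for i in zero]} have no positive entry"
        )
    report = {flat[i]: float(sums[i]) for i in range(len(flat))}
    for i in np.nonzero(np.abs(sums - 1.0) > warn_tol)[0]:
        warnings.warn(
            f"row {flat[i]} sums to {sums[i]:.4f}; normalizing",
            UserWarning,
            stacklevel=2,
        )
    return TwoScaleChain(space=space, P=P / sums[:, None],
                         normalization_report=report, name=name)


def _communicating_classes(P):
    n, labels = connected_components(csr_matrix(P > 0), directed=True,
                                     connection="strong")
    return [np.nonzero(labels == k)[0].tolist() for k in range(n)]


def _check_irreducible(chain_or_P, labels=None):
    P = chain_or_P.P if isinstance(chain_or_P, TwoScaleChain) else np.asarray(chain_or_P)
    classes = _communicating_classes(P)
    if len(classes) > 1:
        if labels is None and isinstance(chain_or_P, TwoScaleChain):
            labels = chain_or_P.space.flat_labels
        named = [
            [labels[i] for i in cls] if labels is not None else cls
            for cls in classes
        ]
        raise ReducibleChainError(
            f"chain is reducible; communicating classes: {named}", classes=named
        )


def _stationary_linear(P):
    n = P.shape[0]
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


def _stationary_power(P, tol=1e-13, max_iter=1_000_000):
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    for _ in range(max_iter):
        nxt = pi @ P
        if np.abs(nxt - pi).sum() < tol:
            return nxt / nxt.sum()
        pi = nxt
    return pi / pi.sum()


def stationary_distribution(chain: TwoScaleChain) -> StationaryDistribution:
    """Left fixed point pi P = pi of an irreducible chain, at flattened level.

    Solved by a constrained linear least-squares solve; if the result is not a
    clean probability vector (near-singular systems), a power-iteration
    fallback is used.  Both routes agree within 1e-9 on well-posed chains.
    """
    _check_irreducible(chain)
    P = chain.P
    pi = _stationary_linear(P)
    if np.any(pi < -1e-10) or abs(pi.sum() - 1.0) > 1e-9 \
            or np.abs(pi @ P - pi).sum() > _ATOL:
        pi = _stationary_power(P)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    return StationaryDistribution(pi, chain.space.flat_labels, level="flat")


def macro_marginal(pi: StationaryDistribution, space: StateSpace) -> StationaryDistribution:
    """Sum flattened stationary mass within each macro block."""
    if pi.level != "flat":
        raise DimensionMismatchError(f"expected flat-level distribution, got {pi.level!r}")
    if len(pi.values) != space.n_flat:
        raise DimensionMismatchError("distribution does not match state space size")
    vals = np.array([
        pi.values[space.block_slice(m)].sum() for m in space.macro_labels
    ])
    return StationaryDistribution(vals, space.macro_labels, level="macro")


def _row_entropies(P):
    # 0 log 0 = 0 by masking
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log2(P), 0.0)
    return -terms.sum(axis=1)


def entropy_rate(chain: TwoScaleChain, pi: StationaryDistribution | None = None) -> float:
    """Entropy rate H = -sum_i pi_i sum_j P_ij log2 P_ij, in bits/day.

    ``pi`` defaults to the chain's stationary distribution.  The value lies in
    [0, log2 n]: 0 for deterministic dynamics, log2 n for i.i.d. uniform.
    """
    if pi is None:
        pi = stationary_distribution(chain)
    if len(pi.values) != chain.n_states:
        raise DimensionMismatchError("pi length does not match chain dimension")
    return float(pi.values @ _row_entropies(chain.P))


def conditional_micro_chain(chain: TwoScaleChain, macro, pi_source="block"):
    """Micro-state dynamics of one macro-state taken in isolation.

    The within-macro block of P is extracted and each row renormalized to sum
    to 1, removing the (rare) leak mass toward other macro-states; this is the
    daily micro-dynamics assuming the macro-state does not change.

    Parameters
    ----------
    pi_source : {"block", "global"}
        "block" (default) returns the stationary vector of the renormalized
        block itself; "global" returns the conditional slice of the full
        chain's stationary distribution, renormalized.

    Returns
    -------
    (P_tilde, pi_tilde) : (ndarray, StationaryDistribution)
    """
    k = chain.space.macro_labels.index(macro)
    micros = chain.space.micro_labels_per_macro[k]
    B = chain.block(macro)
    sums = B.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise AllZeroRowError(
            f"micro-state(s) {[micros[i] for i in zero]} have no within-{macro} "
            "transitions"
        )
    P_tilde = B / sums[:, None]
    if pi_source == "block":
        _check_irreducible(P_tilde, labels=micros)
        pi = _stationary_linear(P_tilde)
        if np.any(pi < -1e-10) or np.abs(pi @ P_tilde - pi).sum() > _ATOL:
            pi = _stationary_power(P_tilde)
        pi = np.clip(pi, 0, None)
        pi /= pi.sum()
    elif pi_source == "global":
        full = stationary_distribution(chain)
        sl = full.values[chain.space.block_slice(macro)]
        pi = sl / sl.sum()
    else:
        raise ValueError(f"unknown pi_source {pi_source!r}")
    return P_tilde, StationaryDistribution(pi, micros, level="micro")


def macro_centric_entropy_rate(chain: TwoScaleChain, macro, pi_source="block") -> float:
    """Entropy rate of the micro dynamics conditional on staying in ``macro``.

    H_M = -sum_i pi~_i sum_j P~_ij log2 P~_ij over the macro's micro alphabet;
    bits/day, bounded by log2 of the number of micro-states.  This is the
    third-order marker: it measures how tightly behaviour is regulated within
    one clinical regime, which global entropy rate averages away.
    """
    P_tilde, pi_tilde = conditional_micro_chain(chain, macro, pi_source=pi_source)
    return float(pi_tilde.values @ _row_entropies(P_tilde))


def total_variation(p, q) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def mixing_time(chain: TwoScaleChain, epsilon: float = 0.25, cap: int = 100_000) -> int:
    """Smallest t with max-over-starts TV(P^t[i,:], pi) <= epsilon, in days.

    A long mixing time is a candidate marker of behavioural inflexibility: the
    number of days before the process forgets its starting condition.  Computed
    by repeated matrix powering; raises once ``cap`` is hit (periodic or
    near-periodic chains never mix).
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must be in (0, 1)")
    pi = stationary_distribution(chain).values
    Pt = chain.P.copy()
    for t in range(1, cap + 1):
        tv = 0.5 * np.abs(Pt - pi).sum(axis=1).max()
        if tv <= epsilon:
            return t
        Pt = Pt @ chain.P
    raise MixingCapReachedError(
        f"TV distance still {tv:.3g} > {epsilon} after {cap} steps"
    )


def mean_recurrence_time(pi: StationaryDistribution, state) -> float:
    """Expected days between returns to ``state``: 1/pi_state.

    Valid for positive-recurrent chains (Kac's formula).  The recurrence time
    of a low-complexity state quantifies the inertia of a maladaptive pattern.
    """
    p = pi[state]
    if p <= 0:
        raise ValueError(f"state {state!r} has zero stationary mass")
    return 1.0 / p


def metrics_report(chain: TwoScaleChain, epsilon: float = 0.25) -> dict:
    """All analytic markers of a chain as a JSON-serializable record.

    First order: macro occupancy.  Second order: global entropy rate.  Third
    order: per-macro macro-centric entropy rates, plus mixing time and mean
    recurrence times.
    """
    pi = stationary_distribution(chain)
    macro_pi = macro_marginal(pi, chain.space)
    try:
        t_mix = mixing_time(chain, epsilon=epsilon)
    except (MixingCapReachedError, ReducibleChainError):
        t_mix = None
    return {
        "stationary_flat": pi.as_dict(),
        "stationary_macro": macro_pi.as_dict(),
        "entropy_rate_bits_per_day": entropy_rate(chain, pi),
        "macro_centric_entropy_rates": {
            m: macro_centric_entropy_rate(chain, m)
            for m in chain.space.macro_labels
        },
        "mixing_time_days": t_mix,
        "mixing_epsilon": epsilon,
        "mean_recurrence_time_days": {
            m: mean_recurrence_time(macro_pi, m) for m in chain.space.macro_labels
        },
        "normalization_report": chain.normalization_report,
        "units": "bits/day",
    }
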