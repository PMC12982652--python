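"""Seeded day-by-day trajectory simulation from a two-time-scale chain.

Free-running trajectories visit (macro, micro) pairs under the full flattened
matrix; conditional simulation draws micro-symbol windows from one macro's
renormalized block chain, emulating observation windows fully contained in a
single clinical regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain import TwoScaleChain, conditional_micro_chain, stationary_distribution


@dataclass(frozen=True)
class Trajectory:
    """A day-indexed (macro, micro) visit sequence with provenance metadata."""

    days: np.ndarray
    macro: np.ndarray
    micro: np.ndarray
    seed: int | None = None
    chain_name: str = ""

    def __len__(self):
        return len(self.days)

    @property
    def flat_labels(self) -> np.ndarray:
        return np.char.add(self.macro.astype(str), self.micro.astype(str))

    def to_frame(self, start_date=None) -> pd.DataFrame:
        df = pd.DataFrame({"day": self.days, "macro": self.macro, "micro": self.micro})
        if start_date is not None:
            df.insert(0, "date", pd.Timestamp(start_date) + pd.to_timedelta(df["day"], "D"))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed=None, chain_name="") -> "Trajectory":
        return cls(
            days=df["day"].to_numpy(dtype=int),
            macro=df["macro"].to_numpy(dtype=object),
            micro=df["micro"].to_numpy(dtype=object),
            seed=seed,
            chain_name=chain_name,
        )


def _sample_path(P, n_steps, start, rng):
    """Markov path via per-row inverse-CDF lookup; returns int state indices."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0  # guard against rounding just below 1
    u = rng.random(n_steps)
    path = np.empty(n_steps + 1, dtype=np.int64)
    path[0] = start
    s = start
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        path[t + 1] = s
    return path


def _initial_state(chain, init, rng):
    if init == "stationary":
        pi = stationary_distribution(chain).values
        return int(rng.choice(chain.n_states, p=pi))
    if isinstance(init, str):
        labels = chain.space.flat_labels
        if init in labels:
            return labels.index(init)
        raise ValueError(f"unknown initial state {init!r}")
    if isinstance(init, tuple) and len(init) == 2:
        return chain.space.flat_index(*init)
    return int(init)


def simulate(chain: TwoScaleChain, n_days: int, seed=None, init="stationary") -> Trajectory:
    """Simulate ``n_days`` daily states; identical seed gives identical output.

    ``init`` may be "stationary" (first state drawn from pi), a flattened
    label such as "DR", a (macro, micro) pair, or a flattened integer index.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    start = _initial_state(chain, init, rng)
    path = _sample_path(chain.P, n_days - 1, start, rng)
    macro_idx = chain.space.macro_of_flat()[path]
    macro = np.array([chain.space.macro_labels[k] for k in range(chain.space.n_macro)],
                     dtype=object)[macro_idx]
    pairs = [chain.space.unflatten(i) for i in range(chain.n_states)]
    micro = np.array([p[1] for p in pairs], dtype=object)[path]
    return Trajectory(days=np.arange(n_days), macro=macro, micro=micro,
                      seed=seed, chain_name=chain.name)


def simulate_conditional(chain: TwoScaleChain, macro, T: int, n_reps: int,
                         seed=None) -> list:
    """Draw ``n_reps`` independent length-``T`` micro-symbol windows.

    Windows are generated directly from the macro's renormalized block chain
    (the process whose entropy rate the macro-centric marker describes), each
    started from the block's stationary distribution.  Replicates use streams
    split deterministically from one seed.
    """
    if T < 2:
        raise ValueError("window length T must be >= 2")
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    if n_reps == 0:
        return []
    P_tilde, pi_tilde = conditional_micro_chain(chain, macro)
    micros = np.array(pi_tilde.labels, dtype=object)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_reps)
    out = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        start = int(rng.choice(len(micros), p=pi_tilde.values))
        path = _sample_path(P_tilde, T - 1, start, rng)
        out.append(micros[path])
    return out


def empirical_macro_occupancy(traj: Trajectory) -> dict:
    """Fraction of days spent in each macro label."""
    labels, counts = np.unique(traj.macro, return_counts=True)
    return {str(l): c / len(traj) for l, c in zip(labels, counts)}


def sojourn_lengths(traj: Trajectory, flat_label: str) -> np.ndarray:
    """Lengths of maximal consecutive runs spent in one flattened state."""
    mask = traj.flat_labels == flat_label
    if not mask.any():
        return np.array([], dtype=int)
    edges = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return ends - starts
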