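"""Symbolization and static information measures over moving windows.

This is the bridge from raw numeric device streams (actigraphy counts, screen
events, heart rate) to discrete symbol streams: ordinal (rank-pattern)
symbolization, plus the classical windowable complexity measures --
approximate entropy, Lempel-Ziv (LZ76) phrase counts and block entropy.
These are second-order ("static") measures; the dynamic markers are built on
top of the symbol streams they produce.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SymbolSeries:
    """An ordered discrete sequence with its alphabet and sampling metadata."""

    symbols: tuple
    alphabet: tuple
    units_per_step: str = "day"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        symbols = tuple(self.symbols)
        alphabet = tuple(self.alphabet)
        extra = set(symbols) - set(alphabet)
        if extra:
            raise ValueError(f"symbols {sorted(map(str, extra))} not in alphabet")
        object.__setattr__(self, "symbols", symbols)
        object.__setattr__(self, "alphabet", alphabet)

    def __len__(self):
        return len(self.symbols)


def ordinal_symbolize(x, order: int = 3) -> SymbolSeries:
    """Map each window of ``order`` consecutive values to its rank pattern.

    The symbol for a window is the permutation that sorts it, written as a
    digit string (e.g. "012" for increasing, "210" for decreasing); ties are
    broken earlier-index-first, so the mapping is deterministic and invariant
    under strictly monotone transforms.  Alphabet size is order!.
    """
    x = np.asarray(x, dtype=float)
    if order < 2:
        raise ValueError("order must be >= 2")
    if x.size < order:
        raise ValueError(f"series of length {x.size} too short for order {order}")
    win = np.lib.stride_tricks.sliding_window_view(x, order)
    # stable argsort = earlier index wins ties
    patterns = np.argsort(win, axis=1, kind="stable")
    symbols = tuple("".join(map(str, row)) for row in patterns)
    alphabet = tuple("".join(map(str, p)) for p in itertools.permutations(range(order)))
    return SymbolSeries(symbols=symbols, alphabet=alphabet,
                        meta={"order": order, "measure": "ordinal"})


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r): regularity of a numeric series (Pincus definition).

    Phi_m - Phi_{m+1} with self-matches included and Chebyshev distance;
    ``r`` defaults to 0.2 times the series standard deviation.  Near 0 for
    regular/periodic signals, larger for irregular ones.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    if r is None:
        r = 0.2 * float(x.std())
    if r <= 0:
        raise ValueError("tolerance r must be > 0")

    def phi(mm):
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        # pairwise Chebyshev distances, vectorized
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        C = (d <= r).mean(axis=1)  # self-match included
        return np.log(C).mean()

    return float(phi(m) - phi(m + 1))


def moving_apply(fn, x, window: int, step: int = 1, **kwargs) -> np.ndarray:
    """Evaluate a scalar measure over sliding windows of a series.

    Output length is floor((n - window) / step) + 1.
    """
    x = np.asarray(x)
    if window < 1 or window > x.size:
        raise ValueError("window must be in [1, len(x)]")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = range(0, x.size - window + 1, step)
    return np.array([fn(x[s:s + window], **kwargs) for s in starts])


def lempel_ziv_complexity(s) -> int:
    """LZ76 exhaustive-history phrase count of a symbol sequence.

    Scans left to right; a new phrase ends whenever the current candidate is
    not reproducible from the prior history by copy-extension.  Grows like
    n / log n for random sequences and stays small for regular ones; invariant
    under alphabet relabeling.
    """
    seq = tuple(s.symbols) if isinstance(s, SymbolSeries) else tuple(s)
    n = len(seq)
    if n == 0:
        raise ValueError("sequence must be nonempty")
    if n == 1:
        return 1
    # reproduction/innovation scan: i walks candidate copy origins in the
    # history, k is the current match length, l the start of the open phrase
    c = 1
    l, i, k, kmax = 1, 0, 1, 1
    while True:
        if seq[i + k - 1] == seq[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            kmax = max(kmax, k)
            i += 1
            if i == l:  # no copy origin reproduces the candidate: new phrase
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i, k, kmax = 0, 1, 1
            else:
                k = 1
    return c


def block_entropy(s, k: int = 1) -> float:
    """Shannon entropy (bits) of the distribution of overlapping k-blocks.

    The increment H_block(k) - H_block(k-1) estimates the conditional entropy
    of the next symbol given k-1 predecessors; for a first-order Markov source
    H_block(2) - H_block(1) converges to the chain's entropy rate.
    """
    seq = tuple(s.symbols) if isinstance(s, SymbolSeries) else tuple(s)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than block length {k}")
    counts = np.array(list(Counter(
        seq[i:i + k] for i in range(len(seq) - k + 1)
    ).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


_DEFAULT_MICRO_ALPHABET = ("R", "W", "N", "F")


def threshold_symbolize(values, thresholds, alphabet=_DEFAULT_MICRO_ALPHABET):
    """Map a numeric feature series onto a micro-symbol alphabet by thresholds.

    Purely illustrative plumbing: len(alphabet) - 1 increasing thresholds bin
    each value into a symbol.  How real device features map onto behavioural
    micro-states is a study-design question, not something this package can
    decide; calibrate the thresholds per deployment.
    """
    thresholds = tuple(thresholds)
    if len(thresholds) != len(alphabet) - 1:
        raise ValueError("need len(alphabet) - 1 thresholds")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    bins = np.digitize(np.asarray(values, dtype=float), thresholds)
    alpha = np.array(alphabet, dtype=object)
    return SymbolSeries(symbols=tuple(alpha[bins]), alphabet=tuple(alphabet),
                        meta={"thresholds": thresholds, "measure": "threshold"})
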