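"""Regime-shift detection on sliding-window entropy-rate series.

When clinical macro-states are not observed, the daily micro-symbol stream
still carries their signature: the entropy rate inside a sliding window
approximates the macro-centric entropy rate of whichever regime the window
sits in.  A shift of regime therefore shows up as a mean shift in the entropy
series, detectable with standard change-point machinery and classifiable by
nearest characteristic entropy level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError
from .estimation import empirical_transition_model, plugin_entropy_rate
from .infodyn import SymbolSeries


@dataclass(frozen=True)
class EntropySeries:
    """Sliding-window entropy-rate estimates indexed by window start day."""

    window_start_day: np.ndarray
    values: np.ndarray
    T: int
    step: int

    def __post_init__(self):
        w = np.asarray(self.window_start_day, dtype=int)
        v = np.asarray(self.values, dtype=float)
        if len(w) != len(v):
            raise ValueError("index and value lengths differ")
        if np.any(np.diff(w) <= 0):
            raise ValueError("window starts must be strictly increasing")
        object.__setattr__(self, "window_start_day", w)
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class ChangePointReport:
    """Detected shifts on an entropy series with per-segment summaries."""

    change_indices: tuple      # window positions, strictly increasing
    change_days: tuple         # same shifts in day coordinates
    segment_means: tuple       # bits/day, one per segment
    segment_regime: tuple      # nearest macro label per segment, or None
    method: str = "cusum"
    threshold: float | None = None
    alpha: float = 0.05
    seed: int | None = None
    n_permutations: int = 1000
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "method": self.method, "threshold": self.threshold,
            "alpha": self.alpha, "seed": self.seed,
            "n_permutations": self.n_permutations,
            "change_indices": list(self.change_indices),
            "change_days": list(map(int, self.change_days)),
            "segment_means": list(map(float, self.segment_means)),
            "segment_regime": list(self.segment_regime),
            **self.meta,
        }


def sliding_entropy_series(s, T: int, step: int = 1, alphabet=None) -> EntropySeries:
    """Plug-in entropy rate over each sliding window of a symbol series."""
    if isinstance(s, SymbolSeries):
        symbols, alphabet = s.symbols, s.alphabet
    else:
        symbols = tuple(s)
        if alphabet is None:
            alphabet = tuple(sorted(set(map(str, symbols))))
    if T < 2:
        raise ValueError("T must be >= 2")
    if len(symbols) < T:
        raise InsufficientDataError(
            f"series of length {len(symbols)} shorter than window T={T}"
        )
    starts = np.arange(0, len(symbols) - T + 1, step)
    vals = np.array([
        plugin_entropy_rate(empirical_transition_model(symbols[s0:s0 + T], alphabet))
        for s0 in starts
    ])
    return EntropySeries(window_start_day=starts, values=vals, T=T, step=step)


def _cusum_stat(x):
    """Max absolute centered cumulative sum and its argmax (candidate shift)."""
    d = x - x.mean()
    S = np.cumsum(d)[:-1]  # split after position k, k = 0..n-2
    k = int(np.argmax(np.abs(S)))
    return float(np.abs(S[k])), k + 1


def _binseg_stat(x):
    """Best single split by within-segment SSE reduction, and the split index."""
    n = len(x)
    total = ((x - x.mean()) ** 2).sum()
    cs, css = np.cumsum(x), np.cumsum(x ** 2)
    k = np.arange(1, n)
    left = css[:-1] - cs[:-1] ** 2 / k
    right = (css[-1] - css[:-1]) - (cs[-1] - cs[:-1]) ** 2 / (n - k)
    gain = total - (left + right)
    j = int(np.argmax(gain))
    return float(gain[j]), j + 1


_STATS = {"cusum": _cusum_stat, "binseg": _binseg_stat}


def _permutation_pvalue(x, stat, stat_fn, rng, n_permutations):
    """Finite-B permutation p-value (observed included), a valid p-value:
    P(p <= alpha) <= alpha under the exchangeable null."""
    exceed = 1
    for _ in range(n_permutations):
        if stat_fn(rng.permutation(x))[0] >= stat:
            exceed += 1
    return exceed / (n_permutations + 1)


def _segment(x, lo, hi, stat_fn, alpha, rng, n_permutations, min_size, out):
    seg = x[lo:hi]
    if len(seg) < 2 * min_size or np.allclose(seg, seg[0]):
        return
    stat, split = stat_fn(seg)
    p = _permutation_pvalue(seg, stat, stat_fn, rng, n_permutations)
    if p <= alpha and min_size <= split <= len(seg) - min_size:
        out.append(lo + split)
        _segment(x, lo, lo + split, stat_fn, alpha, rng, n_permutations, min_size, out)
        _segment(x, lo + split, hi, stat_fn, alpha, rng, n_permutations, min_size, out)


def detect_changepoints(es: EntropySeries, method: str = "cusum",
                        threshold: float | None = None, alpha: float = 0.05,
                        seed=None, n_permutations: int = 1000,
                        min_segment: int = 2,
                        reference: dict | None = None,
                        band: float = 0.0) -> ChangePointReport:
    """Find statistically significant mean shifts in an entropy series.

    "cusum" uses the maximum centered cumulative-sum excursion; "binseg" uses
    the best variance-reducing split.  Either statistic is applied recursively
    (binary segmentation), stopping when a segment's statistic no longer
    exceeds its calibration threshold.

    Calibration: if ``threshold`` is given, a shift is declared where the
    excursion exceeds ``threshold * sd`` of the segment; otherwise the
    threshold is the (1 - alpha) quantile of the statistic over
    ``n_permutations`` seeded reshuffles, which is distribution-free under the
    no-change null.  Detection is invariant to adding a constant to the series.

    ``reference`` (macro label -> analytic macro-centric entropy rate) enables
    per-segment regime classification via :func:`classify_regime`.
    """
    if method not in _STATS:
        raise ValueError(f"unknown method {method!r}; use 'cusum' or 'binseg'")
    x = es.values
    if len(x) < 4:
        raise InsufficientDataError("need at least 4 entropy values")
    stat_fn = _STATS[method]
    rng = np.random.default_rng(seed)
    changes: list[int] = []
    if threshold is not None:
        sd = x.std()
        if sd > 0:
            stat, split = stat_fn(x)
            if stat > threshold * sd and min_segment <= split <= len(x) - min_segment:
                changes.append(split)
    else:
        _segment(x, 0, len(x), stat_fn, alpha, rng, n_permutations,
                 min_segment, changes)
    changes = sorted(changes)
    bounds = [0, *changes, len(x)]
    seg_means = tuple(float(x[a:b].mean()) for a, b in zip(bounds, bounds[1:]))
    regimes = tuple(
        classify_regime(m, reference, band=band) if reference else None
        for m in seg_means
    )
    return ChangePointReport(
        change_indices=tuple(changes),
        change_days=tuple(int(es.window_start_day[c]) for c in changes),
        segment_means=seg_means, segment_regime=regimes,
        method=method, threshold=threshold, alpha=alpha, seed=seed,
        n_permutations=n_permutations,
        meta={"T": es.T, "step": es.step},
    )


def classify_regime(value: float, reference: dict, band: float = 0.0):
    """Nearest macro-state by characteristic entropy level.

    ``reference`` maps macro labels to their analytic macro-centric entropy
    rates (bits/day).  Returns "indeterminate" when two references lie within
    ``band`` of the value; exact ties break deterministically by label order.
    """
    if not reference:
        raise ValueError("reference map must be nonempty")
    labels = sorted(reference)
    dists = {m: abs(value - reference[m]) for m in labels}
    if band > 0 and sum(d <= band for d in dists.values()) >= 2:
        return "indeterminate"
    return min(labels, key=lambda m: (dists[m], labels.index(m)))


def sustained_deviation_alarm(es: EntropySeries, baseline_mean: float,
                              baseline_sd: float, K: int = 3,
                              z: float = 2.0):
    """First window index where K consecutive values leave mean +/- z sd.

    Operationalizes "sustained deviation from baseline entropy" as an online
    alarm rule; returns None if never triggered.
    """
    if K < 1 or baseline_sd < 0:
        raise ValueError("K >= 1 and baseline_sd >= 0 required")
    outside = np.abs(es.values - baseline_mean) > z * baseline_sd
    run = 0
    for i, o in enumerate(outside):
        run = run + 1 if o else 0
        if run >= K:
            return i - K + 1
    return None
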