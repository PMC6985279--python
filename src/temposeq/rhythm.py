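"""Rhythmicity of motif recurrence.

A motif that recurs more than twice (>= 3 occurrences) yields intervals
between its consecutive occurrence starts. Intervals are pooled over all
such motifs of one length into a histogram over the full support
1..(T-n); rhythmicity is the sample standard deviation of the per-interval
counts — a flat histogram (no preferred interval) scores low, a histogram
concentrated on a few intervals (periodic recurrence) scores high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import MotifTable

__all__ = [
    "IntervalHistogram",
    "RhythmTest",
    "interval_histogram",
    "rhythmicity",
    "rhythm_significance",
]


@dataclass
class IntervalHistogram:
    """Pooled histogram of consecutive-occurrence intervals at one motif
    length. ``counts`` maps interval (timepoints >= 1) to occurrence count;
    the support for dispersion statistics is the full range 1..(T-n),
    unobserved intervals counting 0."""

    n: int
    n_timepoints: int
    counts: dict[int, int]

    @property
    def support(self) -> int:
        return self.n_timepoints - self.n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def dense(self) -> np.ndarray:
        """Counts over the full support 1..(T-n), zeros included."""
        vec = np.zeros(self.support, dtype=int)
        for interval, c in self.counts.items():
            vec[interval - 1] = c
        return vec


def interval_histogram(table: MotifTable) -> IntervalHistogram:
    """Pool consecutive-start intervals of every motif with >= 3 occurrences.

    A motif at sorted starts t1 < t2 < ... < tk contributes the k-1 intervals
    t2-t1, ..., tk-t(k-1). Motifs with fewer than 3 occurrences are skipped:
    with a single interval there is nothing to compare for constancy.
    """
    counts: dict[int, int] = {}
    for starts in table.occurrences.values():
        if len(starts) < 3:
            continue
        for a, b in zip(starts, starts[1:]):
            counts[b - a] = counts.get(b - a, 0) + 1
    hist = IntervalHistogram(n=table.n, n_timepoints=table.n_timepoints, counts=counts)
    if counts:
        bad = [i for i in counts if not 1 <= i <= hist.support]
        if bad:
            raise ValueError(f"intervals {bad} outside valid range 1..{hist.support}")
    return hist


def rhythmicity(hist: IntervalHistogram) -> float:
    """Sample SD of per-interval counts over the full support; higher means
    more rhythmic (counts concentrated on few intervals)."""
    if hist.support < 2:
        raise ValueError("interval support must have at least 2 bins")
    return float(hist.dense().std(ddof=1))


@dataclass
class RhythmTest:
    """Per-length surrogate contrast for rhythmicity."""

    n: int
    rhythmicity: float
    surrogate_mean: float
    surrogate_sd: float
    difference: float
    p: float
    p_adjusted: float
    significant: bool
    significant_bins: list[int] = field(default_factory=list)
    rhythmicity_significant_bins: float | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rhythmicity": self.rhythmicity,
            "surrogate_mean": self.surrogate_mean,
            "surrogate_sd": self.surrogate_sd,
            "difference": self.difference,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
            "significant_bins": self.significant_bins,
            "rhythmicity_significant_bins": self.rhythmicity_significant_bins,
        }


def rhythm_significance(
    hist: IntervalHistogram,
    surrogate_hists: list[IntervalHistogram],
    alpha: float = 0.05,
    family_size: int = 8,
) -> RhythmTest:
    """One-tailed surrogate t-test on the rhythmicity SD at one motif length.

    The primary statistic is the SD over all interval bins (the dispersion
    definition). A secondary per-bin screen — one-tailed test of each bin's
    count against the surrogates, Bonferroni across bins — is also computed,
    and the SD restricted to surviving bins is reported alongside.
    """
    from .group_stats import bonferroni, one_tailed_surrogate_test

    if len(surrogate_hists) < 2:
        raise ValueError("need at least 2 surrogate histograms")
    obs = rhythmicity(hist)
    surr = np.array([rhythmicity(h) for h in surrogate_hists])
    test = one_tailed_surrogate_test(obs, surr)
    corr = bonferroni(np.array([test.p]), alpha=alpha, family_size=family_size)

    dense = hist.dense().astype(float)
    surr_dense = np.array([h.dense() for h in surrogate_hists], dtype=float)
    bins: list[int] = []
    if surr_dense.shape[1] == dense.shape[0]:
        per_bin_p = np.array(
            [
                one_tailed_surrogate_test(dense[i], surr_dense[:, i]).p
                for i in range(dense.shape[0])
            ]
        )
        bin_corr = bonferroni(per_bin_p, alpha=alpha)
        bins = [int(i + 1) for i in np.flatnonzero(bin_corr.significant)]
    sd_sig = float(dense[[b - 1 for b in bins]].std(ddof=1)) if len(bins) >= 2 else None

    return RhythmTest(
        n=hist.n,
        rhythmicity=obs,
        surrogate_mean=float(surr.mean()),
        surrogate_sd=float(surr.std(ddof=1)),
        difference=obs - float(surr.mean()),
        p=test.p,
        p_adjusted=float(corr.adjusted[0]),
        significant=bool(corr.significant[0]),
        significant_bins=bins,
        rhythmicity_significant_bins=sd_sig,
    )
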