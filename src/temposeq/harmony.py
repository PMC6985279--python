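"""Harmonicity via the downsample-and-sum spectrum.

The interval histogram doubles as a spectrum: index i (1-based) carries the
number of recurrences at interval i, i.e. amplitude at period i*TR seconds
(frequency 1/(i*TR) Hz). Harmonically related rhythms live at integer
multiples of a fundamental period; decimating the spectrum by factors 2..7
moves each harmonic onto its fundamental, so summing the original with its
decimations amplifies harmonic families. This is the additive analog of the
harmonic product spectrum used in pitch detection. The summed peak index is
reported without a physical frequency assignment — after summation every
point mixes several periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .rhythm import IntervalHistogram

__all__ = [
    "IntervalSpectrum",
    "SummedSpectrum",
    "HarmonicityTest",
    "intervals_to_spectrum",
    "downsample_sum",
    "summed_peak",
    "harmonicity_significance",
    "coincidence_intervals",
]

DEFAULT_FACTORS: tuple[int, ...] = (2, 3, 4, 5, 6, 7)


@dataclass
class IntervalSpectrum:
    """Interval-count spectrum: ``amplitude[i-1]`` is the count at interval i
    (period i*TR seconds, frequency 1/(i*TR) Hz), i = 1..L."""

    amplitude: np.ndarray
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        if amp.ndim != 1:
            raise ValueError("amplitude must be a 1-D vector")
        if (amp < 0).any():
            raise ValueError("amplitudes must be non-negative")
        if amp.size < 7:
            raise ValueError(
                f"spectrum length {amp.size} < 7; downsampling by 7 would be degenerate"
            )
        self.amplitude = amp

    @property
    def length(self) -> int:
        return self.amplitude.size

    def period_seconds(self, index: int) -> float:
        """Period (seconds) of 1-based interval index."""
        return index * self.tr_seconds

    def frequency_hz(self, index: int) -> float:
        """Frequency (Hz) of 1-based interval index."""
        return 1.0 / (index * self.tr_seconds)


@dataclass
class SummedSpectrum:
    """Original spectrum plus its factor-k decimations, summed.

    ``components[k]`` is the factor-k decimation zero-padded to length L
    (k=1 is the original); ``summed`` is their elementwise sum.
    """

    summed: np.ndarray
    components: dict[int, np.ndarray]
    tr_seconds: float = 1.0

    @property
    def length(self) -> int:
        return self.summed.size


def intervals_to_spectrum(
    hist: IntervalHistogram, tr_seconds: float | None = None
) -> IntervalSpectrum:
    """Densify an interval histogram into a spectrum over i = 1..(T-n)."""
    L = hist.support
    if L < 7:
        raise ValueError(f"support T-n={L} < 7: too short for harmonic analysis")
    return IntervalSpectrum(
        amplitude=hist.dense().astype(float),
        tr_seconds=1.0 if tr_seconds is None else tr_seconds,
    )


def downsample_sum(
    spec: IntervalSpectrum, factors: Sequence[int] = DEFAULT_FACTORS
) -> SummedSpectrum:
    """Sum the spectrum with its factor-k decimations (k in ``factors``).

    Decimation keeps every k-th point anchored at index k (1-based):
    component_k[i] = amplitude[k*i] for i = 1..floor(L/k), zero elsewhere.
    A rhythm at period p then contributes to index p from the original and
    from every decimation k with a harmonic partner at period k*p, so
    harmonic families pile up on their fundamental.
    """
    factors = tuple(int(k) for k in factors)
    if any(k < 2 for k in factors):
        raise ValueError("downsampling factors must be >= 2")
    L = spec.length
    if L < max(factors):
        raise ValueError(f"spectrum length {L} < max factor {max(factors)}")
    amp = spec.amplitude
    components: dict[int, np.ndarray] = {1: amp.copy()}
    for k in factors:
        comp = np.zeros(L)
        npts = L // k
        # 1-based: comp[i] = amp[k*i]  ->  0-based comp[i-1] = amp[k*i - 1]
        idx = np.arange(1, npts + 1)
        comp[idx - 1] = amp[k * idx - 1]
        components[k] = comp
    summed = np.sum(list(components.values()), axis=0)
    return SummedSpectrum(summed=summed, components=components, tr_seconds=spec.tr_seconds)


def summed_peak(ss: SummedSpectrum) -> tuple[int, float]:
    """Argmax of the summed spectrum as (1-based index, value).

    Ties break toward the smallest index. A zero spectrum returns (1, 0.0);
    callers should treat a zero peak value as degenerate. The index is not a
    physical frequency — summation mixes periods at every point.
    """
    idx = int(np.argmax(ss.summed))
    return idx + 1, float(ss.summed[idx])


@dataclass
class HarmonicityTest:
    """Per-length surrogate contrast of the summed spectrum."""

    n: int
    n_significant_points: int
    harmonicity_ratio: float | None
    harmonicity_ratio_all_points: float | None
    peak_index: int
    peak_value: float
    per_point_p: np.ndarray
    per_point_p_adjusted: np.ndarray
    significant_points: list[int]
    excluded_zero_surrogate_points: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_significant_points": self.n_significant_points,
            "harmonicity_ratio": self.harmonicity_ratio,
            "harmonicity_ratio_all_points": self.harmonicity_ratio_all_points,
            "peak_index": self.peak_index,
            "peak_value": self.peak_value,
            "significant_points": self.significant_points,
            "excluded_zero_surrogate_points": self.excluded_zero_surrogate_points,
        }


def harmonicity_significance(
    ss: SummedSpectrum,
    surrogate_ss: list[SummedSpectrum],
    alpha: float = 0.05,
    n: int = 0,
) -> HarmonicityTest:
    """Per-point one-tailed surrogate t-tests on the summed spectrum.

    Each of the L points is tested against the surrogate ensemble's values at
    the same point, Bonferroni-corrected across the L points. The
    harmonicity ratio is the mean over significant points of
    observed / surrogate-mean amplitude; points whose surrogate mean is zero
    are excluded from the ratio (it is undefined there) and their count is
    reported. The same ratio over all points is emitted as a secondary value.
    """
    from .group_stats import bonferroni, one_tailed_surrogate_test

    if len(surrogate_ss) < 2:
        raise ValueError("need at least 2 surrogate spectra")
    L = ss.length
    surr = np.array([s.summed for s in surrogate_ss], dtype=float)
    if surr.shape[1] != L:
        raise ValueError("surrogate spectra must share the observed length")
    per_point_p = np.array(
        [one_tailed_surrogate_test(float(ss.summed[i]), surr[:, i]).p for i in range(L)]
    )
    corr = bonferroni(per_point_p, alpha=alpha)
    sig = np.flatnonzero(corr.significant)
    surr_mean = surr.mean(axis=0)

    def _ratio(points: np.ndarray) -> tuple[float | None, int]:
        usable = points[surr_mean[points] > 0]
        excluded = points.size - usable.size
        if usable.size == 0:
            return None, excluded
        return float(np.mean(ss.summed[usable] / surr_mean[usable])), excluded

    ratio_sig, excluded = _ratio(sig)
    ratio_all, _ = _ratio(np.arange(L))
    peak_index, peak_value = summed_peak(ss)
    return HarmonicityTest(
        n=n,
        n_significant_points=int(sig.size),
        harmonicity_ratio=ratio_sig,
        harmonicity_ratio_all_points=ratio_all,
        peak_index=peak_index,
        peak_value=peak_value,
        per_point_p=per_point_p,
        per_point_p_adjusted=corr.adjusted,
        significant_points=[int(i + 1) for i in sig],
        excluded_zero_surrogate_points=int(excluded),
    )


def coincidence_intervals(
    periods: Sequence[int],
    subsets: Iterable[Sequence[int]] | None = None,
) -> dict[tuple[int, ...], int]:
    """First time at which each subset of oscillators realigns.

    Oscillators with integer periods (e.g. seconds) all complete a cycle
    simultaneously at the least common multiple of their periods: periods
    {2, 3} reinforce every 6 s, {2, 5} every 10 s, {2, 3, 5} every 30 s.
    By default every subset of size >= 2 is reported; pass ``subsets``
    (tuples of periods) to restrict.
    """
    periods = tuple(int(p) for p in periods)
    if any(p < 1 for p in periods):
        raise ValueError("periods must be positive integers")
    if subsets is None:
        subsets = [
            combo for r in range(2, len(periods) + 1) for combo in combinations(periods, r)
        ]
    out: dict[tuple[int, ...], int] = {}
    for sub in subsets:
        sub = tuple(sorted(int(p) for p in sub))
        if not sub:
            raise ValueError("subsets must be non-empty")
        if any(p < 1 for p in sub):
            raise ValueError("periods must be positive integers")
        out[sub] = math.lcm(*sub)
    return out
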