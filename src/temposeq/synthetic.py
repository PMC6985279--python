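"""Synthetic fixtures with known ground truth.

Generators emulate the structure the method targets in real scanning data:
an activation series that oscillates among a handful of recurring global
patterns (themes), thematic profiles carrying planted periodic motifs, and
interval spectra with planted harmonic families. Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import child_rng
from .data_io import ImageSeries
from .harmony import IntervalSpectrum
from .themes import ThematicProfile

__all__ = [
    "PlantedTruth",
    "generate_image_series",
    "generate_profile",
    "generate_harmonic_spectrum",
]


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator."""

    seed: int
    theme_labels: np.ndarray | None = None
    motif_plants: list[tuple[tuple[int, ...], list[int], int]] = field(default_factory=list)
    period_family: list[int] = field(default_factory=list)
    noise_sigma: float = 0.0


def _theme_schedule(T: int, K: int, transition_spec, rng: np.random.Generator) -> np.ndarray:
    """Theme label per timepoint (1..K) under a transition model.

    Specs: ("block",) = K contiguous equal blocks; ("periodic", P) = a fixed
    random length-P cycle of themes repeated across T (plants exact period-P
    recurrence of every subsequence of the cycle); ("markov", stay) = sticky
    Markov chain with self-transition probability ``stay``.
    """
    kind = transition_spec[0]
    if kind == "block":
        edges = np.linspace(0, T, K + 1).astype(int)
        labels = np.empty(T, dtype=int)
        for k in range(K):
            labels[edges[k] : edges[k + 1]] = k + 1
        return labels
    if kind == "periodic":
        period = int(transition_spec[1])
        if period < K:
            raise ValueError(f"period {period} shorter than theme count {K}")
        # one full cycle, as balanced across themes as the period allows, so
        # no theme is systematically rare and falls below the edge threshold
        reps = period // K
        cycle = np.concatenate(
            [np.repeat(np.arange(1, K + 1), reps),
             rng.integers(1, K + 1, size=period - K * reps)]
        )
        rng.shuffle(cycle)
        return np.tile(cycle, int(np.ceil(T / period)))[:T]
    if kind == "markov":
        stay = float(transition_spec[1])
        if not 0 <= stay < 1:
            raise ValueError("stay probability must be in [0, 1)")
        labels = np.empty(T, dtype=int)
        labels[0] = rng.integers(1, K + 1)
        for t in range(1, T):
            if rng.random() < stay:
                labels[t] = labels[t - 1]
            else:
                others = [k for k in range(1, K + 1) if k != labels[t - 1]]
                labels[t] = others[rng.integers(len(others))]
        return labels
    raise ValueError(f"unknown transition spec {transition_spec!r}")


def generate_image_series(
    T: int = 300,
    V: int = 500,
    K: int = 5,
    noise_sigma: float = 0.5,
    transition_spec=("block",),
    seed: int = 0,
    tr_seconds: float = 1.0,
) -> tuple[ImageSeries, PlantedTruth]:
    """Activation series built from K prototype patterns plus Gaussian noise.

    Prototypes are random mutually orthogonal feature patterns of equal norm
    (QR of a Gaussian matrix, scaled to unit per-feature variance); each
    timepoint emits its theme's prototype plus i.i.d. N(0, noise_sigma^2)
    noise. Equal prototype norms give every theme the same within-theme
    association strength, so a global top-fraction edge threshold treats
    themes even-handedly — the regime the method assumes of real data.
    Defaults (T=300, V=500, K=5, sigma=0.5) keep a full pipeline run fast
    while preserving T >> K.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if T < K or V < K:
        raise ValueError("need T >= K and V >= K")
    rng = child_rng(seed, 0)
    basis, _ = np.linalg.qr(rng.normal(size=(V, K)))
    prototypes = basis.T * np.sqrt(V)
    labels = _theme_schedule(T, K, transition_spec, rng)
    noise = rng.normal(scale=noise_sigma, size=(T, V)) if noise_sigma > 0 else 0.0
    data = prototypes[labels - 1] + noise
    series = ImageSeries(
        data=data, tr_seconds=tr_seconds, subject_id=f"synthetic-{seed}",
        condition="synthetic",
    )
    truth = PlantedTruth(seed=seed, theme_labels=labels, noise_sigma=noise_sigma)
    return series, truth


def generate_profile(
    T: int,
    alphabet: int,
    motif_plants: list[tuple[tuple[int, ...], int, int, int]] = (),
    background_spec=("iid",),
    seed: int = 0,
    tr_seconds: float = 1.0,
) -> tuple[ThematicProfile, PlantedTruth]:
    """Thematic profile with planted periodic motifs over a random background.

    Each plant is (motif, first_start, period, count): the label sequence
    ``motif`` is written at 1-based starts first_start, first_start+period,
    ..., count times. Instances may not overlap each other (within or across
    plants). Background labels are i.i.d. uniform over 1..alphabet or a
    sticky Markov chain ("markov", stay).
    """
    if alphabet < 1:
        raise ValueError("alphabet must be >= 1")
    rng = child_rng(seed, 0)
    if background_spec[0] == "iid":
        labels = rng.integers(1, alphabet + 1, size=T)
    elif background_spec[0] == "markov":
        labels = _theme_schedule(T, alphabet, ("markov", background_spec[1]), rng)
    else:
        raise ValueError(f"unknown background spec {background_spec!r}")

    occupied = np.zeros(T, dtype=bool)
    plants_out: list[tuple[tuple[int, ...], list[int], int]] = []
    periods: list[int] = []
    for motif, first_start, period, count in motif_plants:
        motif = tuple(int(x) for x in motif)
        if any(not 1 <= x <= alphabet for x in motif):
            raise ValueError(f"motif {motif} uses labels outside 1..{alphabet}")
        starts = [first_start + k * period for k in range(count)]
        for s in starts:
            if not 1 <= s <= T - len(motif) + 1:
                raise ValueError(f"planted instance at {s} does not fit in T={T}")
            span = slice(s - 1, s - 1 + len(motif))
            if occupied[span].any():
                raise ValueError(f"planted instances overlap at start {s}")
            occupied[span] = True
            labels[span] = motif
        plants_out.append((motif, starts, period))
        periods.append(period)
    profile = ThematicProfile(labels=labels, q=float("nan"), tr_seconds=tr_seconds)
    truth = PlantedTruth(
        seed=seed, motif_plants=plants_out, period_family=sorted(set(periods))
    )
    return profile, truth


def generate_harmonic_spectrum(
    L: int,
    fundamental_index: int,
    n_partials: int,
    amplitudes=None,
    noise_level: float = 0.0,
    seed: int = 0,
    tr_seconds: float = 1.0,
) -> IntervalSpectrum:
    """Spectrum with amplitude at {f, 2f, ..., m*f} (a harmonic family).

    ``amplitudes`` defaults to 1 for every partial; ``noise_level`` adds
    uniform integer background counts in [0, noise_level].
    """
    f, m = int(fundamental_index), int(n_partials)
    if f < 1 or m < 1:
        raise ValueError("fundamental index and partial count must be >= 1")
    if f * m > L:
        raise ValueError(f"partial {m}*{f} exceeds spectrum length {L}")
    amp = np.zeros(L)
    if noise_level > 0:
        rng = child_rng(seed, 0)
        amp += rng.integers(0, int(noise_level) + 1, size=L)
    if amplitudes is None:
        amplitudes = np.ones(m)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size != m:
        raise ValueError("need one amplitude per partial")
    for k in range(1, m + 1):
        amp[k * f - 1] += amplitudes[k - 1]
    return IntervalSpectrum(amplitude=amp, tr_seconds=tr_seconds)
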