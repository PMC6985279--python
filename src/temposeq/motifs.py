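"""Exact-match repetition of short theme sequences (motifs).

A motif is a length-n subsequence of the thematic profile. All T-n+1 sliding
windows (overlaps allowed) are grouped by exact label-sequence equality; a
motif that occurs c times contributes c-1 repeats. The per-length repeat
count, normalized by T, is the repetition statistic tested against surrogate
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .themes import ThematicProfile

__all__ = [
    "MotifTable",
    "RepetitionTest",
    "extract_motif_occurrences",
    "count_repeats",
    "repetition_significance",
]


@dataclass
class MotifTable:
    """Occurrences of every length-n window of a profile.

    ``occurrences`` maps each motif (tuple of theme labels) to the sorted
    1-based start timepoints of its occurrences. Every window belongs to
    exactly one motif, so occurrence counts sum to T-n+1.
    """

    n: int
    n_timepoints: int
    occurrences: dict[tuple[int, ...], list[int]]

    @property
    def repeats(self) -> int:
        """Total repeats: sum over motifs of (occurrences - 1)."""
        return sum(len(v) - 1 for v in self.occurrences.values())

    @property
    def repeats_per_length(self) -> float:
        """Repeats normalized by the length of the image series."""
        return self.repeats / self.n_timepoints

    @property
    def matched_pairs(self) -> int:
        """Alternative all-pairs count: sum over motifs of C(occurrences, 2)."""
        return sum(len(v) * (len(v) - 1) // 2 for v in self.occurrences.values())


def extract_motif_occurrences(profile: ThematicProfile, n: int) -> MotifTable:
    """Group all length-n sliding windows of the profile by exact equality.

    Start timepoints are 1-based: the window starting at timepoint t covers
    labels t..t+n-1.
    """
    labels = profile.labels
    T = labels.size
    if not 2 <= n <= T - 1:
        raise ValueError(f"window length n={n} out of range [2, {T - 1}] for T={T}")
    occurrences: dict[tuple[int, ...], list[int]] = {}
    lab = labels.tolist()
    for start in range(T - n + 1):
        motif = tuple(lab[start : start + n])
        occurrences.setdefault(motif, []).append(start + 1)
    return MotifTable(n=n, n_timepoints=T, occurrences=occurrences)


def count_repeats(profile: ThematicProfile, n: int, pairs: bool = False) -> int:
    """Repeat count at window length n; ``pairs`` switches to all-pairs
    counting (every matched window pair counts once)."""
    table = extract_motif_occurrences(profile, n)
    return table.matched_pairs if pairs else table.repeats


@dataclass
class RepetitionTest:
    """Per-length surrogate contrast for the repetition statistic."""

    n: int
    observed_repeats: int
    repeats_per_length: float
    surrogate_mean: float
    surrogate_sd: float
    p: float
    p_adjusted: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "observed_repeats": self.observed_repeats,
            "repeats_per_length": self.repeats_per_length,
            "surrogate_mean": self.surrogate_mean,
            "surrogate_sd": self.surrogate_sd,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
        }


def repetition_significance(
    profile: ThematicProfile,
    surrogate_profiles: list[ThematicProfile],
    n: int,
    alpha: float = 0.05,
    family_size: int = 8,
    pairs: bool = False,
) -> RepetitionTest:
    """One-tailed surrogate t-test on the repeat count at length n.

    The Bonferroni family is the set of tested motif lengths (8 by default:
    n = 4..11), applied per subject and per measure.
    """
    from .group_stats import bonferroni, one_tailed_surrogate_test

    if len(surrogate_profiles) < 2:
        raise ValueError("need at least 2 surrogate profiles")
    table = extract_motif_occurrences(profile, n)
    observed = table.matched_pairs if pairs else table.repeats
    surr = np.array(
        [count_repeats(sp, n, pairs=pairs) for sp in surrogate_profiles], dtype=float
    )
    test = one_tailed_surrogate_test(float(observed), surr)
    corr = bonferroni(np.array([test.p]), alpha=alpha, family_size=family_size)
    return RepetitionTest(
        n=n,
        observed_repeats=int(observed),
        repeats_per_length=observed / profile.n_timepoints,
        surrogate_mean=float(surr.mean()),
        surrogate_sd=float(surr.std(ddof=1)),
        p=test.p,
        p_adjusted=float(corr.adjusted[0]),
        significant=bool(corr.significant[0]),
    )
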