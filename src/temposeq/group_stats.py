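"""Shared statistics: one-tailed surrogate t-tests, Bonferroni correction,
and cohort summaries.

The surrogate test compares one observed value to an ensemble of values
computed by the identical pipeline on null surrogates: t is the observed
value's z-score against the surrogate mean/SD, referred to Student's t with
n_surrogates - 1 degrees of freedom, upper tail (alternative: observed
greater than the null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurrogateTest",
    "BonferroniResult",
    "one_tailed_surrogate_test",
    "bonferroni",
    "cohort_summary",
]


@dataclass
class SurrogateTest:
    observed: float
    surrogate_mean: float
    surrogate_sd: float
    n_surrogates: int
    t: float
    p: float
    degenerate: bool = False
    tail: str = "observed greater"


def one_tailed_surrogate_test(observed: float, surrogates) -> SurrogateTest:
    """t = (observed - mean(surrogates)) / sd(surrogates), upper-tail p at
    df = n - 1.

    With zero surrogate SD the t-score is undefined; p degrades to 0/0.5/1
    according to the sign of observed - common value, flagged degenerate.
    """
    surrogates = np.asarray(surrogates, dtype=float)
    n = surrogates.size
    if n < 2:
        raise ValueError("need at least 2 surrogate values")
    mean = float(surrogates.mean())
    sd = float(surrogates.std(ddof=1))
    if sd == 0:
        if observed > mean:
            p = 0.0
        elif observed < mean:
            p = 1.0
        else:
            p = 0.5
        return SurrogateTest(
            observed=float(observed), surrogate_mean=mean, surrogate_sd=0.0,
            n_surrogates=n, t=np.inf if observed != mean else 0.0, p=p, degenerate=True,
        )
    t = (float(observed) - mean) / sd
    p = float(stats.t.sf(t, df=n - 1))
    return SurrogateTest(
        observed=float(observed), surrogate_mean=mean, surrogate_sd=sd,
        n_surrogates=n, t=t, p=p,
    )


@dataclass
class BonferroniResult:
    adjusted: np.ndarray
    significant: np.ndarray
    family_size: int
    alpha: float


def bonferroni(
    p_values, alpha: float = 0.05, family_size: int | None = None
) -> BonferroniResult:
    """Bonferroni correction: adjusted = min(1, p * m); significant iff
    adjusted < alpha.

    ``family_size`` defaults to len(p_values) but can be set larger when the
    vector is one member of a wider family (e.g. one motif length out of 8).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(family_size) if family_size is not None else p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    adjusted = np.minimum(1.0, p * m)
    return BonferroniResult(
        adjusted=adjusted, significant=adjusted < alpha, family_size=m, alpha=alpha
    )


def cohort_summary(
    per_subject_records: dict[int, list[dict]],
    measure: str,
) -> pd.DataFrame:
    """Cohort grid: per motif length, % significant subjects and the
    mean/SD/SEM of ``measure``.

    ``per_subject_records`` maps motif length n to a list of per-subject
    dicts, each carrying at least ``measure`` and ``significant``. Single-
    subject cohorts get null SD/SEM (flagged by the n_subjects column).
    """
    if not per_subject_records:
        raise ValueError("empty cohort")
    rows = []
    for n in sorted(per_subject_records):
        records = per_subject_records[n]
        if not records:
            raise ValueError(f"no records for length {n}")
        vals = np.array([float(r[measure]) for r in records])
        n_sig = sum(bool(r["significant"]) for r in records)
        k = len(records)
        sd = float(vals.std(ddof=1)) if k > 1 else None
        rows.append(
            {
                "n": n,
                "n_subjects": k,
                "percent_significant": 100.0 * n_sig / k,
                "mean": float(vals.mean()),
                "sd": sd,
                "sem": (sd / np.sqrt(k)) if sd is not None else None,
            }
        )
    return pd.DataFrame(rows).set_index("n")
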