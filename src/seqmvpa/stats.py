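"""Group-level inference utilities: one-sample t-tests, Cohen's d, Bonferroni."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class DegenerateTestError(ValueError):
    """Raised when the sample variance is zero and the t statistic undefined."""


@dataclass(frozen=True)
class GroupStatResult:
    t: float
    df: int
    p_uncorrected: float
    p_corrected: float
    cohens_d: float
    tails: str
    bonferroni_m: int
    mu: float = 0.0


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p value, capped at 1."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return min(1.0, m * p)


def one_sample_t(
    values: np.ndarray,
    mu: float = 0.0,
    tails: str = "two",
    bonferroni_m: int = 1,
) -> GroupStatResult:
    """One-sample t-test of ``values`` against ``mu``.

    ``tails='one'`` tests the alternative mean > mu.  Cohen's d is
    (mean - mu) / SD with the n-1 sample standard deviation.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateTestError("zero sample variance; t statistic undefined")
    mean = float(x.mean())
    t = (mean - mu) / (sd / math.sqrt(n))
    df = n - 1
    if tails == "one":
        p = float(sps.t.sf(t, df))
    else:
        p = float(2.0 * sps.t.sf(abs(t), df))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return GroupStatResult(
        t=t,
        df=df,
        p_uncorrected=p,
        p_corrected=bonferroni(p, bonferroni_m),
        cohens_d=(mean - mu) / sd,
        tails=tails,
        bonferroni_m=bonferroni_m,
        mu=mu,
    )
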