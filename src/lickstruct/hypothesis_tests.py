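"""Two-sample tests and the log transform used by the analysis battery.

All statistics are computed from first principles; scipy contributes only
distribution functions (t, normal) and midrank assignment.  Two-sided p
values throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError


@dataclass(frozen=True)
class TestResult:
    """Generic hypothesis-test result.

    Attributes
    ----------
    name : str
        Statistic name: "U", "t", "z" or "beta".
    value : float
        The statistic.  For Mann-Whitney this is min(U1, U2); both U values
        are in ``extra``.
    df : float or None
        Degrees of freedom where applicable.
    n1, n2 : int or None
        Group sizes.
    p : float
        Two-sided p value.
    adjusted_p : float or None
        Multiplicity-adjusted p (Bonferroni), when part of a family.
    """

    name: str
    value: float
    p: float
    df: float | None = None
    n1: int | None = None
    n2: int | None = None
    adjusted_p: float | None = None
    label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p value {self.p} outside [0, 1]")

    def __str__(self):
        bits = [f"{self.name} = {self.value:.4g}"]
        if self.df is not None:
            bits.append(f"df = {self.df:g}")
        bits.append(f"p = {self.p:.4g}")
        if self.adjusted_p is not None:
            bits.append(f"adj. p = {self.adjusted_p:.4g}")
        prefix = f"{self.label}: " if self.label else ""
        return prefix + ", ".join(bits)


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def unpaired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pooled-variance two-sample t test, df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValidationError("unpaired t needs at least 2 observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValidationError("zero pooled variance; t statistic undefined")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * float(sps.t.sf(abs(t), df))
    return TestResult(name="t", value=float(t), p=p, df=float(df), n1=n1, n2=n2)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired t on the within-unit differences, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("paired t needs samples of equal length")
    d = x - y
    n = len(d)
    if n < 2:
        raise ValidationError("paired t needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult(name="t", value=0.0, p=1.0, df=float(n - 1),
                              n1=n, n2=n)
        raise ValidationError("zero variance of differences; t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * float(sps.t.sf(abs(t), n - 1))
    return TestResult(name="t", value=float(t), p=p, df=float(n - 1), n1=n, n2=n)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_rank_sum_counts(n1: int, n2: int) -> np.ndarray:
    """Number of n1-subsets of ranks {1..n1+n2} attaining each rank sum.

    counts[s] = #subsets with sum s, s = 0 .. n1*(n1+n2).  Dynamic programme
    over ranks; only feasible sums are ever non-zero.
    """
    N = n1 + n2
    max_sum = n1 * N
    f = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    f[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            f[k, r:] += f[k - 1, : max_sum + 1 - r]
    return f[n1]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Mann-Whitney U from rank sums with midranks for ties.

    The statistic reported is min(U1, U2); U1 + U2 = n1 * n2 always.  The
    exact two-sided p is computed by enumerating rank configurations (a
    subset-sum count, not brute force) when the combined sample is small
    (n1 + n2 <= 20) and tie-free; otherwise the normal approximation with tie
    and continuity corrections is used — the convention of standard
    statistics packages, so a 14-vs-15 comparison takes the normal path.
    """
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if mode == "exact" or (mode == "auto" and n1 + n2 <= 20 and not has_ties):
        if has_ties:
            raise ValidationError("exact Mann-Whitney p undefined with ties")
        counts = _exact_rank_sum_counts(n1, n2)
        total = counts.sum()
        offset = n1 * (n1 + 1) / 2.0
        u_of_sum = np.arange(counts.size) - offset   # U1 per rank sum
        p_low = counts[u_of_sum <= u + 1e-12].sum() / total
        p = min(1.0, 2.0 * p_low)                    # U distribution is symmetric
        method = "exact"
    else:
        N = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(((tie_counts ** 3) - tie_counts).sum()) / (N * (N - 1))
        sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            # continuity correction toward the mean; u <= mu by construction
            z = (u - mu + 0.5) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * float(sps.norm.cdf(z)))
        method = "normal_approx"
    return TestResult(
        name="U", value=float(u), p=float(p), n1=n1, n2=n2,
        extra={"U1": float(u1), "U2": float(u2), "method": method},
    )


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def log_transform(values: Sequence[float], labels: Sequence | None = None) -> np.ndarray:
    """Natural log; rejects non-positive inputs, naming the offending units."""
    v = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(v > 0))
    if bad.size:
        if labels is not None:
            names = [labels[i] for i in bad[:10]]
        else:
            names = bad[:10].tolist()
        raise ValidationError(
            f"log transform requires strictly positive values; offending units: {names}"
        )
    return np.log(v)
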