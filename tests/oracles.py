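"""Independent oracles used by the test suite.

These are deliberately naive re-derivations of quantities the package
computes by other means:

* ``naive_segment`` — O(n^2) cluster segmentation by forward scanning;
* ``glm_projection_anova`` — mixed-ANOVA sums of squares from incremental
  residual sums of squares of nested least-squares fits (a general-linear-
  model projection, no cell-mean formulas);
* ``brute_force_mwu_exact_p`` — exact two-sided Mann-Whitney p by literal
  enumeration of all rank assignments;
* ``log_odds_ratio`` — closed-form 2x2 slope for logistic regression.

They share no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


def naive_segment(timestamps, threshold: float) -> list[list[float]]:
    """Quadratic segmentation: for each lick, scan for its cluster mates.

    A lick j joins the cluster of lick i iff every adjacent gap between them
    is < threshold (compared at 0.01 s resolution, like the implementation's
    stated boundary rule).
    """
    ts = list(timestamps)
    n = len(ts)
    clusters: list[list[float]] = []
    s = 0
    while s < n:
        # scan forward from the cluster start, re-deriving every gap from the
        # raw timestamps each time (pure-Python, no shared code with the
        # vectorized implementation)
        e = s
        while e + 1 < n and round(ts[e + 1] - ts[e], 2) < threshold - 1e-9:
            e += 1
        clusters.append([ts[i] for i in range(s, e + 1)])
        s = e + 1
    return clusters


def glm_projection_anova(
    df: pd.DataFrame,
    unit: str,
    between: str,
    within: tuple[str, ...],
    response: str,
) -> dict[str, dict]:
    """Mixed-ANOVA strata via nested least-squares projections.

    Terms are added hierarchically (between, subjects, then each within
    effect and its error stratum); each stratum's SS is the drop in residual
    SS when its dummy columns join the model, its df the rank increase.  For
    balanced designs this equals the classical decomposition regardless of
    order.  Returns {term: {"ss", "df"}} plus "residual"; term keys:
    A, S, B, AB, BS, C, AC, CS, BC, ABC.
    """
    y = df[response].to_numpy(dtype=float)

    def dummies(cols: tuple[str, ...]) -> np.ndarray:
        key = df[list(cols)].astype(str).agg("|".join, axis=1)
        return pd.get_dummies(key).to_numpy(dtype=float)

    terms: list[tuple[str, tuple[str, ...]]] = [("A", (between,)), ("S", (unit,))]
    if len(within) >= 1:
        B = within[0]
        terms += [("B", (B,)), ("AB", (between, B)), ("BS", (unit, B))]
    if len(within) == 2:
        C = within[1]
        terms += [
            ("C", (C,)), ("AC", (between, C)), ("CS", (unit, C)),
            ("BC", (B, C)), ("ABC", (between, B, C)),
        ]

    X = np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    prev_rss = float(((y - X @ beta) ** 2).sum())
    prev_rank = 1
    out: dict[str, dict] = {}
    for name, cols in terms:
        X = np.hstack([X, dummies(cols)])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        out[name] = {"ss": prev_rss - rss, "df": int(rank) - prev_rank}
        prev_rss, prev_rank = rss, int(rank)
    out["residual"] = {"ss": prev_rss, "df": len(y) - prev_rank}
    return out


def glm_f(oracle: dict, effect: str, error: str) -> float:
    e, r = oracle[effect], oracle[error]
    return (e["ss"] / e["df"]) / (r["ss"] / r["df"])


def brute_force_mwu_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every rank assignment.

    Feasible for n1 + n2 <= 12 or so; requires tie-free data.
    """
    x = list(x)
    y = list(y)
    n1, n2 = len(x), len(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "ties not supported"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs_1 = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    u_obs = min(u_obs_1, n1 * n2 - u_obs_1)

    count = 0
    total = 0
    for subset in itertools.combinations(range(1, n1 + n2 + 1), n1):
        u1 = sum(subset) - n1 * (n1 + 1) / 2
        u = min(u1, n1 * n2 - u1)
        total += 1
        if u <= u_obs + 1e-12:
            count += 1
    return min(1.0, count / total)


def log_odds_ratio(n_event_a: int, n_a: int, n_event_b: int, n_b: int) -> float:
    """Closed-form 2x2 log odds ratio (B relative to A)."""
    odds_a = n_event_a / (n_a - n_event_a)
    odds_b = n_event_b / (n_b - n_event_b)
    return math.log(odds_b / odds_a)
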