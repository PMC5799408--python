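"""Binary logistic regression fitted by iteratively reweighted least squares.

Used for the "did the mouse defecate" outcomes: a binary response per animal
regressed on the two-level handling factor.  With a single binary predictor
the maximum-likelihood slope equals the log odds ratio of the 2x2 table, a
closed form the tests exploit as an oracle.  Complete separation (a zero
cell in the 2x2 table) admits no finite MLE; it is detected up front and
flagged rather than letting IRLS diverge quietly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import SeparationError, ValidationError
from .hypothesis_tests import TestResult


class BinaryLogit:
    """Logistic model of a binary outcome on a design matrix.

    Parameters
    ----------
    endog : array of 0/1
    exog : 2-D array including the intercept column.
    """

    def __init__(self, endog: Sequence[int], exog: np.ndarray):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if set(np.unique(self.endog)) - {0.0, 1.0}:
            raise ValidationError("outcome must be binary 0/1")
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValidationError("endog and exog lengths differ")

    def fit(self, max_iter: int = 100, tol: float = 1e-10) -> "BinaryLogitResults":
        X, y = self.exog, self.endog
        beta = np.zeros(X.shape[1])
        for _ in range(max_iter):
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            w = np.clip(w, 1e-12, None)
            z = eta + (y - p) / w
            XtW = X.T * w
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
            if np.max(np.abs(beta_new - beta)) < tol:
                beta = beta_new
                break
            beta = beta_new
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        cov = np.linalg.inv((X.T * w) @ X)
        return BinaryLogitResults(beta, cov, n=len(y))


class BinaryLogitResults:
    """Coefficients, their Wald standard errors and p values."""

    def __init__(self, params: np.ndarray, cov: np.ndarray, n: int):
        self.params = params
        self.cov = cov
        self.bse = np.sqrt(np.diag(cov))
        self.n = n

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * sps.norm.sf(np.abs(self.zvalues))

    def summary(self) -> str:
        lines = ["Binary logistic regression (IRLS)",
                 f"  n = {self.n}",
                 f"{'':<12}{'coef':>10}{'se':>10}{'z':>8}{'p':>9}"]
        names = ["intercept"] + [f"x{i}" for i in range(1, len(self.params))]
        for name, b, se, z, p in zip(names, self.params, self.bse,
                                     self.zvalues, self.pvalues):
            lines.append(f"{name:<12}{b:>10.4f}{se:>10.4f}{z:>8.3f}{p:>9.4f}")
        return "\n".join(lines)


def binary_logistic(
    outcome: Sequence[int], group: Sequence
) -> TestResult:
    """Regress a per-unit binary outcome on a two-level factor.

    Returns the slope (log odds ratio of group2 relative to group1, the
    groups taken in sorted order) with its Wald p value.  Complete
    separation raises :class:`SeparationError` — no finite estimate exists
    and none is reported.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    g = np.asarray(group)
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ValidationError(f"group must have exactly 2 levels, got {levels}")
    x = (g == levels[1]).astype(float)

    # 2x2 table: zero cell <=> complete (quasi-)separation on this predictor
    table = np.array(
        [[np.sum((x == gx) & (y == yy)) for yy in (0, 1)] for gx in (0, 1)]
    )
    if (table == 0).any():
        raise SeparationError(
            f"complete separation: 2x2 table {table.tolist()} has a zero cell; "
            "no finite slope exists"
        )

    X = np.column_stack([np.ones_like(x), x])
    res = BinaryLogit(y, X).fit()
    return TestResult(
        name="beta",
        value=float(res.params[1]),
        p=float(res.pvalues[1]),
        n1=int(np.sum(x == 0)),
        n2=int(np.sum(x == 1)),
        extra={
            "intercept": float(res.params[0]),
            "se": float(res.bse[1]),
            "z": float(res.zvalues[1]),
            "levels": levels,
            "table": table.tolist(),
        },
    )
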