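"""Balanced mixed-design (repeated-measures) ANOVA and Bonferroni post hocs.

The model is the classical univariate mixed-model decomposition for one
between-subject factor A (subjects nested in its levels) and one or two
within-subject factors, fully crossed with subjects:

* the between effect A is tested against the subjects-within-groups stratum
  S(A);
* each within effect W, and its interaction A x W, is tested against the
  W x S(A) stratum;
* with two within factors B and C, the B x C and A x B x C effects are
  tested against B x C x S(A).

Only *balanced* designs — equal subjects per group, every subject observed
in every within cell exactly once — are accepted.  Unbalanced layouts are
rejected with an explicit error rather than approximated: for balanced data
the Type I/II/III sums-of-squares distinction vanishes, so the decomposition
is unambiguous; for unbalanced data it is not, and silently picking one
would invite misuse.

Degrees of freedom are reported uncorrected by default (matching how
two-level within factors are conventionally reported); a Greenhouse-Geisser
sphericity correction is available for a single within factor with more than
two levels via ``fit(gg=True)``.

The API follows the model/results convention: build a :class:`MixedAnova`
from a long-format DataFrame and a :class:`DesignSpec`, call ``fit()``, and
read the effect table off the returned :class:`MixedAnovaResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, ValidationError
from .hypothesis_tests import TestResult, log_transform, paired_t, unpaired_t

_SS_ATOL = 1e-12


@dataclass(frozen=True)
class DesignSpec:
    """Declares the columns and roles of a mixed-design layout.

    Parameters
    ----------
    unit : str
        Column naming the experimental unit (mouse or cage).
    between : str
        Column of the between-subject factor (e.g. handling method).
    within : tuple of str
        Zero, one or two within-subject factor columns (e.g. sucrose
        concentration; session day).
    response : str
        Response column.
    transform : {"none", "log"}
        Applied to the response before fitting.  ``log`` is the natural log
        and requires strictly positive responses.
    """

    unit: str
    between: str
    within: tuple[str, ...] = ()
    response: str = "value"
    transform: str = "none"

    def __post_init__(self):
        object.__setattr__(self, "within", tuple(self.within))
        if len(self.within) > 2:
            raise ValidationError("at most two within-subject factors supported")
        if self.transform not in ("none", "log"):
            raise ValidationError(f"unknown transform {self.transform!r}")


class MixedAnova:
    """Balanced mixed-design ANOVA model.

    Parameters
    ----------
    data : DataFrame
        Long format: one row per unit per within cell.
    design : DesignSpec

    Examples
    --------
    >>> spec = DesignSpec(unit="subject_id", between="handling",
    ...                   within=("concentration",), response="mean_mass")
    >>> res = MixedAnova(df, spec).fit()
    >>> res.anova_table  # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, design: DesignSpec):
        self.design = design
        self.data = self._validate(data.copy())

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        unit: str,
        between: str,
        within: Sequence[str] = (),
        response: str = "value",
        transform: str = "none",
    ) -> "MixedAnova":
        return cls(data, DesignSpec(unit, between, tuple(within), response, transform))

    # -- validation ---------------------------------------------------------

    def _validate(self, df: pd.DataFrame) -> pd.DataFrame:
        d = self.design
        needed = [d.unit, d.between, *d.within, d.response]
        for col in needed:
            if col not in df.columns:
                raise DesignError(f"missing column {col!r}")
        if not np.all(np.isfinite(df[d.response].to_numpy(dtype=float))):
            raise ValidationError("response contains non-finite values")

        # each unit sits in exactly one between level
        lvl_per_unit = df.groupby(d.unit)[d.between].nunique()
        bad = lvl_per_unit[lvl_per_unit > 1]
        if len(bad):
            raise DesignError(
                f"unit {bad.index[0]!r} appears in multiple {d.between} levels"
            )

        # balance: equal number of units per between level
        units_per_group = df.groupby(d.between)[d.unit].nunique()
        if units_per_group.nunique() > 1:
            worst = units_per_group.idxmin()
            raise DesignError(
                f"unbalanced design: {d.between}={worst!r} has "
                f"{units_per_group[worst]} units vs {units_per_group.max()} elsewhere"
            )

        # completeness: every unit observed once in every within cell
        if d.within:
            counts = df.groupby([d.unit, *d.within], observed=True).size()
            if (counts != 1).any():
                unit_cell = counts[counts != 1].index[0]
                raise DesignError(
                    f"unit/cell {unit_cell!r} observed {int(counts[counts != 1].iloc[0])} "
                    "times; balanced designs need exactly one observation per cell"
                )
            expected = 1
            for w in d.within:
                expected *= df[w].nunique()
            per_unit = df.groupby(d.unit).size()
            if (per_unit != expected).any():
                u = per_unit[per_unit != expected].index[0]
                raise DesignError(f"unit {u!r} is missing within cells")
        else:
            per_unit = df.groupby(d.unit).size()
            if (per_unit != 1).any():
                raise DesignError(
                    "purely between-subject design needs one observation per unit"
                )
        return df

    # -- fitting ------------------------------------------------------------

    def fit(self, gg: bool = False) -> "MixedAnovaResults":
        d = self.design
        df = self.data
        y = df[d.response].to_numpy(dtype=float)
        if d.transform == "log":
            units = df[d.unit].tolist()
            y = log_transform(y, labels=units)
        work = df.assign(__y=y)

        if len(d.within) == 0:
            table = self._fit_between_only(work)
        elif len(d.within) == 1:
            table = self._fit_one_within(work, gg=gg)
        else:
            if gg:
                raise ValidationError(
                    "Greenhouse-Geisser correction implemented for a single "
                    "within factor only"
                )
            table = self._fit_two_within(work)

        n_per_group = int(work.groupby(d.between)[d.unit].nunique().iloc[0])
        return MixedAnovaResults(self, table, n_per_group=n_per_group)

    @staticmethod
    def _frow(ss_eff, df_eff, ss_err, df_err):
        """F and p with the degenerate cases made explicit: a zero effect SS is
        F = 0 / p = 1 (even against a zero error stratum); a positive effect
        against zero error is reported as infinite F."""
        ms_eff = ss_eff / df_eff if df_eff else np.nan
        ms_err = ss_err / df_err if df_err else np.nan
        if ss_eff <= _SS_ATOL:
            return ms_eff, 0.0, 1.0
        if not np.isfinite(ms_err) or ms_err <= _SS_ATOL:
            return ms_eff, np.inf, 0.0
        f = ms_eff / ms_err
        return ms_eff, f, float(sps.f.sf(f, df_eff, df_err))

    def _fit_between_only(self, work: pd.DataFrame) -> pd.DataFrame:
        d = self.design
        y = work["__y"].to_numpy()
        g = y.mean()
        ss_total = float(((y - g) ** 2).sum())
        gm = work.groupby(d.between)["__y"].mean()
        n = int(work.groupby(d.between).size().iloc[0])
        a = len(gm)
        ss_a = float(n * ((gm - g) ** 2).sum())
        ss_err = ss_total - ss_a
        df_a, df_err = a - 1, a * (n - 1)
        ms_a, f_a, p_a = self._frow(ss_a, df_a, ss_err, df_err)
        rows = [
            (d.between, ss_a, df_a, ms_a, f_a, p_a, "subjects(within groups)"),
            ("subjects(within groups)", ss_err, df_err,
             ss_err / df_err if df_err else np.nan, np.nan, np.nan, ""),
        ]
        return _table(rows, ss_total, len(y))

    def _fit_one_within(self, work: pd.DataFrame, gg: bool) -> pd.DataFrame:
        d = self.design
        A, B, U = d.between, d.within[0], d.unit
        y = work["__y"].to_numpy()
        g = y.mean()
        ss_total = float(((y - g) ** 2).sum())

        b = work[B].nunique()
        a = work[A].nunique()
        n = int(work.groupby(A)[U].nunique().iloc[0])

        m_s = work.groupby(U)["__y"].mean()
        m_a = work.groupby(A)["__y"].mean()
        m_b = work.groupby(B)["__y"].mean()
        m_ab = work.groupby([A, B])["__y"].mean()

        ss_a = float(n * b * ((m_a - g) ** 2).sum())
        ss_subj = float(b * ((m_s - g) ** 2).sum())
        ss_swa = ss_subj - ss_a

        ss_b = float(a * n * ((m_b - g) ** 2).sum())
        dev_ab = m_ab.copy()
        for (la, lb), v in m_ab.items():
            dev_ab.loc[(la, lb)] = v - m_a[la] - m_b[lb] + g
        ss_ab = float(n * (dev_ab ** 2).sum())
        ss_bs = ss_total - ss_a - ss_swa - ss_b - ss_ab

        df_a, df_swa = a - 1, a * (n - 1)
        df_b, df_ab = b - 1, (a - 1) * (b - 1)
        df_bs = a * (n - 1) * (b - 1)

        eps = 1.0
        if gg and b > 2:
            eps = self._gg_epsilon(work)
        ms_a, f_a, p_a = self._frow(ss_a, df_a, ss_swa, df_swa)
        ms_b, f_b, _ = self._frow(ss_b, df_b, ss_bs, df_bs)
        ms_ab, f_ab, _ = self._frow(ss_ab, df_ab, ss_bs, df_bs)
        # GG rescales the df used for the p value; F itself is unchanged
        p_b = _f_p(f_b, eps * df_b, eps * df_bs)
        p_ab = _f_p(f_ab, eps * df_ab, eps * df_bs)

        err_b = f"{B} x subjects(within groups)"
        rows = [
            (A, ss_a, df_a, ms_a, f_a, p_a, "subjects(within groups)"),
            ("subjects(within groups)", ss_swa, df_swa,
             ss_swa / df_swa if df_swa else np.nan, np.nan, np.nan, ""),
            (B, ss_b, df_b, ms_b, f_b, p_b, err_b),
            (f"{A} x {B}", ss_ab, df_ab, ms_ab, f_ab, p_ab, err_b),
            (err_b, ss_bs, df_bs, ss_bs / df_bs if df_bs else np.nan,
             np.nan, np.nan, ""),
        ]
        return _table(rows, ss_total, len(y))

    def _fit_two_within(self, work: pd.DataFrame) -> pd.DataFrame:
        d = self.design
        A, U = d.between, d.unit
        B, C = d.within
        y = work["__y"].to_numpy()
        g = y.mean()
        ss_total = float(((y - g) ** 2).sum())

        a, b, c = work[A].nunique(), work[B].nunique(), work[C].nunique()
        n = int(work.groupby(A)[U].nunique().iloc[0])
        unit_group = work.groupby(U)[A].first()

        m_s = work.groupby(U)["__y"].mean()
        m_a = work.groupby(A)["__y"].mean()
        m_b = work.groupby(B)["__y"].mean()
        m_c = work.groupby(C)["__y"].mean()
        m_ab = work.groupby([A, B])["__y"].mean()
        m_ac = work.groupby([A, C])["__y"].mean()
        m_bc = work.groupby([B, C])["__y"].mean()
        m_abc = work.groupby([A, B, C])["__y"].mean()
        m_sb = work.groupby([U, B])["__y"].mean()
        m_sc = work.groupby([U, C])["__y"].mean()

        ss_a = float(n * b * c * ((m_a - g) ** 2).sum())
        ss_subj = float(b * c * ((m_s - g) ** 2).sum())
        ss_swa = ss_subj - ss_a

        ss_b = float(a * n * c * ((m_b - g) ** 2).sum())
        ss_ab = float(n * c * sum(
            (m_ab[(la, lb)] - m_a[la] - m_b[lb] + g) ** 2
            for la, lb in m_ab.index
        ))
        ss_bs = float(c * sum(
            (m_sb[(s, lb)] - m_s[s] - m_ab[(unit_group[s], lb)] + m_a[unit_group[s]]) ** 2
            for s, lb in m_sb.index
        ))

        ss_c = float(a * n * b * ((m_c - g) ** 2).sum())
        ss_ac = float(n * b * sum(
            (m_ac[(la, lc)] - m_a[la] - m_c[lc] + g) ** 2
            for la, lc in m_ac.index
        ))
        ss_cs = float(b * sum(
            (m_sc[(s, lc)] - m_s[s] - m_ac[(unit_group[s], lc)] + m_a[unit_group[s]]) ** 2
            for s, lc in m_sc.index
        ))

        ss_bc = float(a * n * sum(
            (m_bc[(lb, lc)] - m_b[lb] - m_c[lc] + g) ** 2
            for lb, lc in m_bc.index
        ))
        ss_abc = float(n * sum(
            (
                m_abc[(la, lb, lc)]
                - m_ab[(la, lb)] - m_ac[(la, lc)] - m_bc[(lb, lc)]
                + m_a[la] + m_b[lb] + m_c[lc] - g
            ) ** 2
            for la, lb, lc in m_abc.index
        ))
        ss_bcs = ss_total - (
            ss_a + ss_swa + ss_b + ss_ab + ss_bs + ss_c + ss_ac + ss_cs + ss_bc + ss_abc
        )

        df_a, df_swa = a - 1, a * (n - 1)
        df_b, df_ab, df_bs = b - 1, (a - 1) * (b - 1), a * (n - 1) * (b - 1)
        df_c, df_ac, df_cs = c - 1, (a - 1) * (c - 1), a * (n - 1) * (c - 1)
        df_bc, df_abc = (b - 1) * (c - 1), (a - 1) * (b - 1) * (c - 1)
        df_bcs = a * (n - 1) * (b - 1) * (c - 1)

        err_b = f"{B} x subjects(within groups)"
        err_c = f"{C} x subjects(within groups)"
        err_bc = f"{B} x {C} x subjects(within groups)"
        rows = []
        for name, ss, dfe, ss_e, df_e, err in [
            (A, ss_a, df_a, ss_swa, df_swa, "subjects(within groups)"),
            (B, ss_b, df_b, ss_bs, df_bs, err_b),
            (f"{A} x {B}", ss_ab, df_ab, ss_bs, df_bs, err_b),
            (C, ss_c, df_c, ss_cs, df_cs, err_c),
            (f"{A} x {C}", ss_ac, df_ac, ss_cs, df_cs, err_c),
            (f"{B} x {C}", ss_bc, df_bc, ss_bcs, df_bcs, err_bc),
            (f"{A} x {B} x {C}", ss_abc, df_abc, ss_bcs, df_bcs, err_bc),
        ]:
            ms, f, p = self._frow(ss, dfe, ss_e, df_e)
            rows.append((name, ss, dfe, ms, f, p, err))
        for name, ss, dfe in [
            ("subjects(within groups)", ss_swa, df_swa),
            (err_b, ss_bs, df_bs),
            (err_c, ss_cs, df_cs),
            (err_bc, ss_bcs, df_bcs),
        ]:
            rows.append((name, ss, dfe, ss / dfe if dfe else np.nan,
                         np.nan, np.nan, ""))
        # keep error strata adjacent to the effects they serve
        order = [0, 7, 1, 2, 8, 3, 4, 9, 5, 6, 10]
        rows = [rows[i] for i in order]
        return _table(rows, ss_total, len(y))

    def _gg_epsilon(self, work: pd.DataFrame) -> float:
        """Greenhouse-Geisser epsilon from the pooled within-group covariance
        of the within-factor scores."""
        d = self.design
        B, U, A = d.within[0], d.unit, d.between
        wide = work.pivot_table(index=U, columns=B, values="__y")
        groups = work.groupby(U)[A].first()
        mats = []
        for _, idx in groups.groupby(groups).groups.items():
            sub = wide.loc[idx].to_numpy()
            mats.append(np.cov(sub, rowvar=False, ddof=1))
        S = np.mean(mats, axis=0)
        b = S.shape[0]
        # orthonormal contrasts
        C = np.linalg.qr(np.eye(b) - 1.0 / b)[0][:, : b - 1]
        M = C.T @ S @ C
        eps = (np.trace(M) ** 2) / ((b - 1) * np.trace(M @ M))
        return float(min(1.0, max(eps, 1.0 / (b - 1))))


def _f_p(f: float, df1: float, df2: float) -> float:
    if not np.isfinite(f):
        return 0.0 if f == np.inf else np.nan
    if f == 0.0:
        return 1.0
    return float(sps.f.sf(f, df1, df2))


def _table(rows, ss_total: float, n_obs: int) -> pd.DataFrame:
    tab = pd.DataFrame(
        rows, columns=["effect", "SS", "df", "MS", "F", "p", "error_stratum"]
    ).set_index("effect")
    # decomposition identity: strata exhaust the total SS and N-1 df
    assert abs(tab["SS"].sum() - ss_total) < 1e-6 * max(1.0, ss_total), "SS leak"
    assert int(tab["df"].sum()) == n_obs - 1, "df leak"
    return tab


class MixedAnovaResults:
    """Holds the effect table of a fitted :class:`MixedAnova`.

    Attributes
    ----------
    anova_table : DataFrame
        Indexed by effect; columns SS, df, MS, F, p, error_stratum.  Error
        strata appear as rows with no F.
    n_per_group : int
        Units per between-factor level.
    """

    def __init__(self, model: MixedAnova, table: pd.DataFrame, n_per_group: int):
        self.model = model
        self.design = model.design
        self.anova_table = table
        self.n_per_group = n_per_group

    def effect(self, name: str) -> pd.Series:
        return self.anova_table.loc[name]

    def f_statistic(self, name: str) -> float:
        return float(self.anova_table.loc[name, "F"])

    def p_value(self, name: str) -> float:
        return float(self.anova_table.loc[name, "p"])

    def pairwise(self, comparisons: Sequence["Comparison"]) -> list[TestResult]:
        return bonferroni_pairwise(self.model.data, self.design, comparisons)

    def summary(self) -> str:
        d = self.design
        lines = [
            "Mixed-design ANOVA",
            f"  response: {d.response}"
            + (f" ({d.transform}-transformed)" if d.transform != "none" else ""),
            f"  between:  {d.between}; within: {', '.join(d.within) or '(none)'}",
            f"  units:    {d.unit} (n = {self.n_per_group} per group)",
            "",
            f"{'effect':<42}{'SS':>12}{'df':>5}{'MS':>12}{'F':>10}{'p':>9}",
        ]
        for name, row in self.anova_table.iterrows():
            f = "" if not np.isfinite(row["F"]) else f"{row['F']:.3f}"
            p = "" if not np.isfinite(row["p"]) else _fmt_p(row["p"])
            lines.append(
                f"{name:<42}{row['SS']:>12.4f}{int(row['df']):>5}"
                f"{row['MS']:>12.4f}{f:>10}{p:>9}"
            )
        return "\n".join(lines)

    def __repr__(self):
        return f"<MixedAnovaResults: {len(self.anova_table)} strata>"


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# Bonferroni pairwise comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Comparison:
    """One pairwise comparison in a Bonferroni family.

    Parameters
    ----------
    factor : str
        Factor whose levels are compared.
    levels : tuple, optional
        The pair of levels; default = the factor's two levels (error if more).
    where : mapping, optional
        Restriction to a slice of the other factors, e.g. the simple effect
        of handling at concentration 4 is
        ``Comparison("handling", where={"concentration": 4})``.
    paired : bool, optional
        Paired (within-unit) or unpaired t.  Default: paired when ``factor``
        is a within-subject factor of the design.
    label : str
        Free-text label carried into the report.
    """

    factor: str
    levels: tuple | None = None
    where: Mapping | None = None
    paired: bool | None = None
    label: str = ""


def bonferroni_pairwise(
    data: pd.DataFrame,
    design: DesignSpec,
    family: Sequence[Comparison],
) -> list[TestResult]:
    """Pairwise t comparisons with Bonferroni adjustment over the family.

    The family is the set of comparisons requested for one effect (e.g. the
    two handling simple effects, one per concentration); each raw two-sided p
    is multiplied by the family size and capped at 1.  Paired vs unpaired is
    dictated by whether the compared factor varies within or between units.

    Responses are aggregated to one value per unit (mean) within each slice
    before testing, and the design's transform is applied.
    """
    if not family:
        raise ValidationError("empty comparison family")
    m = len(family)
    results = []
    for comp in family:
        sub = data
        if comp.where:
            for col, val in comp.where.items():
                if col not in sub.columns:
                    raise ValidationError(f"unknown column {col!r} in comparison")
                sub = sub[sub[col] == val]
        if comp.factor not in sub.columns:
            raise ValidationError(f"unknown factor {comp.factor!r}")
        levels = comp.levels or tuple(pd.unique(sub[comp.factor]))
        if len(levels) != 2:
            raise ValidationError(
                f"comparison on {comp.factor!r} needs exactly 2 levels, got {levels}"
            )
        for lv in levels:
            if lv not in set(sub[comp.factor]):
                raise ValidationError(
                    f"level {lv!r} not present in factor {comp.factor!r}"
                )
        paired = comp.paired
        if paired is None:
            paired = comp.factor in design.within

        per_unit = (
            sub.groupby([design.unit, comp.factor], observed=True)[design.response]
            .mean()
            .unstack(comp.factor)
        )
        x = per_unit[levels[0]].dropna()
        y = per_unit[levels[1]].dropna()
        if design.transform == "log":
            x = pd.Series(log_transform(x.to_numpy(), labels=x.index.tolist()), index=x.index)
            y = pd.Series(log_transform(y.to_numpy(), labels=y.index.tolist()), index=y.index)
        if paired:
            common = x.index.intersection(y.index)
            res = paired_t(x.loc[common].to_numpy(), y.loc[common].to_numpy())
        else:
            res = unpaired_t(x.to_numpy(), y.to_numpy())
        label = comp.label or (
            f"{comp.factor}: {levels[0]} vs {levels[1]}"
            + (f" | {dict(comp.where)}" if comp.where else "")
        )
        results.append(
            replace(res, adjusted_p=min(1.0, m * res.p), label=label)
        )
    return results


def mixed_anova(data: pd.DataFrame, design: DesignSpec, gg: bool = False) -> MixedAnovaResults:
    """Functional wrapper: fit a balanced mixed-design ANOVA in one call."""
    return MixedAnova(data, design).fit(gg=gg)


def assumption_checks(data: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Normality (Shapiro-Wilk per cell) and variance homogeneity (Levene
    across between-groups per within cell) diagnostics.

    These *report and warn only* — they never switch the test that is run:
    the analysis applied to a dataset is whatever the config says, so two
    runs of one config always use identical procedures.  A warning is logged
    for every p < 0.05.

    Returns a tidy frame: cell, check ("shapiro" | "levene"), statistic, p.
    """
    import logging

    logger = logging.getLogger(__name__)
    d = design
    y = data[d.response].to_numpy(dtype=float)
    if d.transform == "log":
        y = log_transform(y, labels=data[d.unit].tolist())
    work = data.assign(__y=y)
    cells = [d.between, *d.within] if d.within else [d.between]
    rows = []
    for cell, sub in work.groupby(cells, observed=True):
        vals = sub["__y"].to_numpy()
        if len(vals) >= 3 and np.ptp(vals) > 0:
            w, p = sps.shapiro(vals)
            rows.append({"cell": str(cell), "check": "shapiro",
                         "statistic": float(w), "p": float(p)})
            if p < 0.05:
                logger.warning("Shapiro-Wilk flags non-normality in cell %s "
                               "(p = %.3g); test choice unchanged", cell, p)
    within_cells = list(d.within) if d.within else []
    grouper = within_cells if within_cells else (lambda _: 0)
    for cell, sub in work.groupby(grouper, observed=True):
        groups = [g["__y"].to_numpy() for _, g in sub.groupby(d.between)]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            w, p = sps.levene(*groups)
            rows.append({"cell": str(cell), "check": "levene",
                         "statistic": float(w), "p": float(p)})
            if p < 0.05:
                logger.warning("Levene flags variance heterogeneity at %s "
                               "(p = %.3g); test choice unchanged", cell, p)
    return pd.DataFrame(rows)
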