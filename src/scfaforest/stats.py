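"""Two-group comparisons and Spearman correlation matrices.

Continuous variables are compared with a t-test when both groups pass a
Shapiro-Wilk normality screen (alpha = 0.05) and with the Mann-Whitney U test
otherwise; categorical variables with Fisher's exact test (2x2 tables with a
small expected cell) or the chi-square test.  Correlation structure between
markers and nutrients is summarised as a Spearman matrix with significance
flags at p <= 0.05 and p < 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .tables import DIET_GROUPS


@dataclass
class TestResult:
    variable: str
    test: str  # mann_whitney | t_test | chi2 | fisher
    statistic: float
    pvalue: float
    group_summaries: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "variable": self.variable,
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
        }
        for g, s in self.group_summaries.items():
            row[g] = s
        return row


def _clean(values) -> np.ndarray:
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    return x


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.2f} (±{np.std(x, ddof=1):.2f})"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}–{q3:.2f})"


def compare_continuous(x, y, method: str = "auto", variable: str = "") -> TestResult:
    """Compare a continuous variable between two groups.

    ``auto`` runs a Shapiro-Wilk screen (alpha = 0.05) on both groups and uses
    the t-test only when both pass; otherwise Mann-Whitney U (exact p for
    tie-free samples of size <= 8, tie-corrected normal approximation above).
    """
    a, b = _clean(x), _clean(y)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"insufficient data for variable {variable!r}")
    if method not in ("auto", "mann_whitney", "t_test"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        normal = sps.shapiro(a).pvalue > 0.05 and sps.shapiro(b).pvalue > 0.05
        method = "t_test" if normal else "mann_whitney"
    if method == "t_test":
        res = sps.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        summaries = {g: _summary(v, True) for g, v in zip(DIET_GROUPS, (a, b))}
    else:
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        exact = max(len(a), len(b)) <= 8 and not ties
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        stat, p = float(res.statistic), float(res.pvalue)
        summaries = {g: _summary(v, False) for g, v in zip(DIET_GROUPS, (a, b))}
    return TestResult(variable=variable, test=method, statistic=stat, pvalue=p,
                      group_summaries=summaries)


def compare_categorical(table, variable: str = "") -> TestResult:
    """Chi-square or Fisher exact test on a 2 x k contingency table.

    Fisher's exact test is used for 2x2 tables with any expected cell of at
    most 5; otherwise the chi-square test without continuity correction.
    """
    t = np.asarray(table)
    if t.size == 0:
        raise ValueError("empty contingency table")
    if (t < 0).any() or not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValueError("contingency cells must be non-negative integers")
    if t.sum() == 0:
        raise ValueError("contingency table sums to zero")
    expected = sps.contingency.expected_freq(t)
    if t.shape == (2, 2) and (expected <= 5).any():
        odds, p = sps.fisher_exact(t)
        return TestResult(variable=variable, test="fisher", statistic=float(odds),
                          pvalue=float(p))
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(variable=variable, test="chi2", statistic=float(chi2), pvalue=float(p))


def compare_groups_table(
    metadata: pd.DataFrame,
    variables,
    group_col: str = "diet_group",
    method: str = "auto",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-variable two-group tests over metadata columns (listwise missing handling).

    ``adjust='bh'`` appends Benjamini-Hochberg adjusted p-values.
    """
    groups = metadata[group_col]
    rows = []
    for var in variables:
        col = metadata[var]
        if col.dtype == object or str(col.dtype) == "category":
            ct = pd.crosstab(groups, col).to_numpy()
            rows.append(compare_categorical(ct, variable=var).as_row())
        else:
            a = col[groups == DIET_GROUPS[0]]
            b = col[groups == DIET_GROUPS[1]]
            rows.append(compare_continuous(a, b, method=method, variable=var).as_row())
    out = pd.DataFrame(rows).set_index("variable")
    if adjust == "bh":
        out["pvalue_bh"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


@dataclass
class CorrelationMatrix:
    """Spearman r/p matrices with Fig-style significance flags."""

    r: pd.DataFrame
    p: pd.DataFrame
    flags: pd.DataFrame  # '**' p < 0.0001, '*' p <= 0.05, '' otherwise, 'x' undefined

    @property
    def variables(self) -> list[str]:
        return list(self.r.columns)


def spearman_matrix(frame: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations with two-sided t-approximation p.

    Constant columns yield undefined correlations, reported as NaN and flagged
    ``'x'``.
    """
    cols = list(frame.columns)
    n = len(cols)
    r = np.eye(n)
    p = np.zeros((n, n))
    undef = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            pair = frame[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"need >=3 paired observations for {cols[i]!r} vs {cols[j]!r}"
                )
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() == 1 or y.nunique() == 1:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                undef[i, j] = undef[j, i] = True
                continue
            res = sps.spearmanr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    flags = pd.DataFrame("", index=cols, columns=cols)
    flags = flags.mask(pdf <= 0.05, "*").mask(pdf < 0.0001, "**")
    flags = flags.mask(pd.DataFrame(undef, index=cols, columns=cols), "x")
    np.fill_diagonal(flags.values, "")
    return CorrelationMatrix(r=rdf, p=pdf, flags=flags)
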