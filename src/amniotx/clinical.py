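"""Clinical characteristics table: Welch's t, Fisher's exact, summaries.

Continuous variables are summarized as median (Q1-Q3) per group, with
linearly interpolated (type-7) quartiles, and compared by Welch's
unequal-variance t test.  Categorical variables are summarized as
count/denominator (%) using non-missing denominators and compared by the
two-sided Fisher's exact test, with the two-sided p defined as the sum
of hypergeometric point probabilities (over tables with the observed
margins) no larger than that of the observed table — the convention
needed to reproduce published clinical-table p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = study groups, columns = condition
    present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 or int(x) != x for x in counts):
            raise ValueError("counts must be nonnegative integers")
        if sum(counts) == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Tables with the observed margins whose hypergeometric probability is
    at most that of the observed table (within a 1e-7 relative tolerance
    for floating-point ties) contribute to p.  A zero row or column
    margin gives p = 1 with a warning.
    """
    arr = (table.as_array() if isinstance(table, ContingencyTable2x2)
           else np.asarray(table, dtype=int))
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("a table margin is zero: p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: returns (t, df, two-sided p).

    The degrees of freedom follow the Welch-Satterthwaite approximation.
    Two constant samples with equal means give (0, nx+ny-2, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 non-missing values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return np.inf, float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    return float(med), float(q1), float(q3)


def summarize_cohort(
    samples: pd.DataFrame,
    variables: dict[str, str],
    group_by: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Build a two-group clinical characteristics table.

    ``variables`` maps column names to ``"continuous"`` or
    ``"categorical"`` (categorical columns must be binary / boolean).
    Summaries use non-missing denominators; each row carries the matching
    test's p-value and a significance flag at ``alpha``.
    """
    groups = samples[group_by].dropna().unique().tolist()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g1, g2 = sorted(groups)

    rows = []
    for var, kind in variables.items():
        if var not in samples.columns:
            raise ValueError(f"unknown variable {var!r}")
        if kind not in ("continuous", "categorical"):
            raise ValueError(f"variable {var!r}: kind must be continuous or categorical")
        sub = samples[[group_by, var]]
        x = sub.loc[sub[group_by] == g1, var]
        y = sub.loc[sub[group_by] == g2, var]
        if x.notna().sum() == 0 and y.notna().sum() == 0:
            rows.append({"variable": var, "type": kind, "summary_" + g1: "missing",
                         "summary_" + g2: "missing", "p": np.nan,
                         "significant": False})
            continue
        if kind == "continuous":
            xs = x.dropna().to_numpy(dtype=float)
            ys = y.dropna().to_numpy(dtype=float)
            m1, q11, q31 = _quartiles(xs)
            m2, q12, q32 = _quartiles(ys)
            _, _, p = welch_t(xs, ys)
            s1 = f"{m1:g} ({q11:g}-{q31:g})"
            s2 = f"{m2:g} ({q12:g}-{q32:g})"
        else:
            xb = x.dropna().astype(bool)
            yb = y.dropna().astype(bool)
            a, b = int(xb.sum()), int((~xb).sum())
            c, d = int(yb.sum()), int((~yb).sum())
            p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            s1 = f"{a}/{a + b} ({100 * a / (a + b):.1f}%)" if a + b else "missing"
            s2 = f"{c}/{c + d} ({100 * c / (c + d):.1f}%)" if c + d else "missing"
        rows.append({"variable": var, "type": kind, "summary_" + g1: s1,
                     "summary_" + g2: s2, "p": p, "significant": bool(p < alpha)})
    return pd.DataFrame(rows).set_index("variable")
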