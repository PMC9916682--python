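"""Clinical statistics of the phenotypes: endotheliopathy classification,
D-versus-rest group tests, Kaplan-Meier survival and cohort summary tables.

Group comparisons contrast phenotype D against the other phenotypes pooled;
numeric variables use Kruskal-Wallis, categorical variables Pearson's
chi-square (no Yates continuity correction by default — the policy is a flag
and is echoed in the result). Medians and IQRs use the linear-interpolation
quantile convention used repo-wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import EOT_SYNDECAN1_THRESHOLD, FOLLOW_UP_DAYS


def eot_classify(syndecan1):
    """Endotheliopathy-of-trauma flag: syndecan-1 ≥ 40 ng/mL (inclusive).

    Accepts scalars or arrays; missing values yield missing flags.
    """
    if np.isscalar(syndecan1):
        if syndecan1 is None or (isinstance(syndecan1, float) and np.isnan(syndecan1)):
            return np.nan
        if syndecan1 < 0:
            raise ValueError("syndecan-1 must be non-negative")
        return bool(syndecan1 >= EOT_SYNDECAN1_THRESHOLD)
    arr = pd.Series(syndecan1, dtype=float)
    if (arr.dropna() < 0).any():
        raise ValueError("syndecan-1 must be non-negative")
    out = (arr >= EOT_SYNDECAN1_THRESHOLD).astype("boolean")
    return out.mask(arr.isna())


@dataclass
class GroupTestResult:
    variable: str
    test: str            # kruskal | chi2
    statistic: float
    p_value: float
    continuity_correction: bool = False


def group_tests(table: pd.DataFrame, variable: str, labels: pd.Series,
                d_label: str = "D", categorical: bool | None = None,
                continuity_correction: bool = False) -> GroupTestResult:
    """D-vs-rest contrast for one variable.

    Numeric → Kruskal-Wallis H on the two pooled groups; categorical/boolean →
    Pearson chi-square on the 2×L contingency table.
    """
    labels = labels.loc[table.index]
    values = table[variable]
    in_d = labels == d_label
    if not in_d.any() or in_d.all():
        raise ValueError("both D and non-D groups must be non-empty")
    if categorical is None:
        categorical = (values.dtype == bool
                       or not pd.api.types.is_numeric_dtype(values))
    if categorical:
        contingency = pd.crosstab(in_d, values)
        chi2, p, _, _ = stats.chi2_contingency(
            contingency.to_numpy(), correction=continuity_correction)
        return GroupTestResult(variable, "chi2", float(chi2), float(p),
                               continuity_correction)
    d_vals = values[in_d].dropna()
    rest = values[~in_d].dropna()
    if len(d_vals) == 0 or len(rest) == 0:
        raise ValueError("empty group after dropping missing values")
    if np.array_equal(np.sort(d_vals), np.sort(rest)):
        # identical samples: H = 0, p = 1 (scipy raises on all-tied input)
        return GroupTestResult(variable, "kruskal", 0.0, 1.0)
    h, p = stats.kruskal(d_vals, rest)
    return GroupTestResult(variable, "kruskal", float(h), float(p))


def km_estimate(times, events, group) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per group, censored at 30 days.

    Returns, per group, a step-function frame with columns ``time`` and
    ``survival`` (lifelines estimator underneath).
    """
    from lifelines import KaplanMeierFitter

    times = pd.Series(times, dtype=float).clip(upper=FOLLOW_UP_DAYS)
    events = pd.Series(list(events), index=times.index).astype(bool)
    group = pd.Series(list(group), index=times.index)
    curves = {}
    for g in group.unique():
        sel = group == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[g] = sf
    return curves


def survival_at(curve: pd.DataFrame, t: float) -> float:
    """Step-function evaluation of a km_estimate curve at time t."""
    past = curve[curve["time"] <= t]
    return float(past["survival"].iloc[-1]) if len(past) else 1.0


def summarize_cohort(table: pd.DataFrame, labels: pd.Series,
                     variables: list[str] | None = None) -> pd.DataFrame:
    """Per-phenotype summary: median [Q1, Q3] numeric, n (%) categorical."""
    labels = labels.loc[table.index]
    if variables is None:
        variables = [c for c in table.columns if c != "phenotype"]
    phenos = sorted(labels.unique())
    rows = {}
    for var in variables:
        vals = table[var]
        rec = {}
        for ph in phenos:
            sub = vals[labels == ph].dropna()
            if vals.dtype == bool or not pd.api.types.is_numeric_dtype(vals):
                n = int((sub == True).sum()) if sub.dtype == bool else len(sub)  # noqa: E712
                total = int((labels == ph).sum())
                pct = 100.0 * n / total if total else 0.0
                rec[ph] = f"{n} ({pct:.1f}%)"
            else:
                if len(sub) == 0:
                    rec[ph] = "–"
                else:
                    med, q1, q3 = np.quantile(sub, [0.5, 0.25, 0.75])
                    rec[ph] = f"{med:.3g} [{q1:.3g}, {q3:.3g}]"
        rows[var] = rec
    return pd.DataFrame(rows).T[phenos]


def count_share(counts: dict[str, int], phenotype: str = "D") -> float:
    """Percentage share of one phenotype in a count table (e.g. 72-h deaths)."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no events")
    return 100.0 * counts[phenotype] / total


def rate_percent(count: int, total: int) -> float:
    """Simple percentage with the conventions used in the summary tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * count / total
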