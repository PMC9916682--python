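"""Metabolomics preprocessing: missingness filter, imputation, normalization,
perfect-correlate removal and PCA-based outlier detection.

The canonical pipeline order is fixed: metabolites missing in more than 30% of
samples are excluded; remaining gaps are imputed with an iterative
random-forest scheme; values are log2-transformed and Pareto-scaled; one
member of every (near-)perfectly correlated metabolite pair is dropped;
samples outside the 95% Hotelling-T² ellipse on the (PC1, PC2) or (PC1, PC3)
score planes are removed. A single removal pass, no refit loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PreprocessReport:
    excluded_metabolites: list[str] = field(default_factory=list)
    dropped_correlates: list[tuple[str, str]] = field(default_factory=list)  # (kept, dropped)
    n_imputed: int = 0
    outliers: dict[str, dict] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "excluded_metabolites": self.excluded_metabolites,
            "dropped_correlates": [list(p) for p in self.dropped_correlates],
            "n_imputed": self.n_imputed,
            "outliers": self.outliers,
            "params": self.params,
        }


def filter_missingness(matrix: pd.DataFrame, threshold: float = 0.30
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Drop metabolites missing in strictly more than ``threshold`` of samples."""
    if matrix.empty:
        raise ValueError("empty concentration matrix")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    frac = matrix.isna().mean(axis=0)
    excluded = [m for m in matrix.columns if frac[m] > threshold]
    if len(excluded) == len(matrix.columns):
        raise ValueError("all metabolites exceed the missingness threshold")
    return matrix.drop(columns=excluded), excluded


def impute_missing(matrix: pd.DataFrame, seed: int,
                   n_estimators: int = 30, max_iter: int = 10
                   ) -> pd.DataFrame:
    """Iterative random-forest imputation (missForest-style).

    Missing cells start at per-metabolite medians; metabolites are then cycled
    in order of increasing missingness, each regressed on all others with a
    random forest, until the imputed values stabilize or ``max_iter`` rounds.
    Observed cells are never modified; the result is deterministic in ``seed``.
    """
    fully_missing = [m for m in matrix.columns if matrix[m].isna().all()]
    if fully_missing:
        raise ValueError(
            f"fully missing metabolites (filter first): {fully_missing}")
    low_support = [m for m in matrix.columns if matrix[m].notna().sum() < 2]
    if low_support:
        raise ValueError(f"metabolites with < 2 observed values: {low_support}")
    if not matrix.isna().any().any():
        return matrix.copy()

    from sklearn.ensemble import RandomForestRegressor
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    estimator = RandomForestRegressor(n_estimators=n_estimators,
                                      random_state=seed, n_jobs=1)
    imputer = IterativeImputer(estimator=estimator, max_iter=max_iter,
                               initial_strategy="median",
                               imputation_order="ascending",
                               sample_posterior=False, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny gaps
        values = imputer.fit_transform(matrix.to_numpy(dtype=float))
    out = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    # guarantee observed cells are untouched
    observed = matrix.notna()
    out = out.where(~observed, matrix)
    return out


def log2_pareto(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 transform then Pareto scaling: (x − mean)/√sd per metabolite.

    Mean and sample standard deviation (ddof 1) are computed on the log2
    values. Constant columns cannot be scaled; they map to zero with a
    warning. Non-positive values are an error naming the offending cell.
    """
    bad = matrix.le(0)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(f"non-positive value at sample {row!r}, "
                         f"metabolite {col!r}: {matrix.loc[row, col]}")
    logged = np.log2(matrix.astype(float))
    centered = logged - logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant metabolites scaled to zero: {constant}",
                      stacklevel=2)
    divisor = np.sqrt(sd.replace(0, np.nan))
    out = centered / divisor
    out[constant] = 0.0
    return out


def drop_perfect_correlates(matrix: pd.DataFrame, r_threshold: float = 0.999
                            ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop the later column of every |Pearson r| ≥ threshold pair.

    Columns are scanned in order; a column correlated with any *retained*
    earlier column is dropped, so a triple of identical columns loses two.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix must be imputed before correlate removal")
    corr = matrix.corr().abs()
    retained: list[str] = []
    dropped_pairs: list[tuple[str, str]] = []
    for col in matrix.columns:
        partner = next((kept for kept in retained
                        if corr.loc[kept, col] >= r_threshold), None)
        if partner is None:
            retained.append(col)
        else:
            dropped_pairs.append((partner, col))
    return matrix[retained], dropped_pairs


def detect_outliers_pca(matrix: pd.DataFrame, alpha: float = 0.05,
                        ) -> tuple[list[str], pd.DataFrame]:
    """Samples outside the (1 − alpha) Hotelling-T² ellipse on PC1-2 or PC1-3.

    The score ellipse uses the classical F reference
    T²_crit = p(n−1)(n+1)/(n(n−p)) · F(1−alpha; p, n−p) with p = 2. Returns the
    flagged sample ids and the per-sample statistics for both planes.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("need at least 3 samples")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    _, svals, _Vt = np.linalg.svd(X, full_matrices=False)
    scores = X @ _Vt.T
    rank = int((svals > 1e-10 * svals[0]).sum()) if svals.size else 0
    if rank < 3:
        warnings.warn(f"input rank {rank} < 3; using available components",
                      stacklevel=2)
    var = (svals ** 2) / (n - 1)
    p = 2
    crit = (p * (n - 1) * (n + 1)) / (n * (n - p)) * stats.f.ppf(1 - alpha, p, n - p)
    planes = [(0, 1)] + ([(0, 2)] if rank >= 3 else [])
    stats_rows = {}
    flagged = []
    for sid, row in zip(matrix.index, scores):
        rec = {}
        is_out = False
        for a, b in planes:
            t2 = row[a] ** 2 / var[a] + row[b] ** 2 / var[b]
            rec[f"t2_pc{a + 1}{b + 1}"] = float(t2)
            if t2 > crit:
                is_out = True
        rec["t2_crit"] = float(crit)
        stats_rows[sid] = rec
        if is_out:
            flagged.append(sid)
    return flagged, pd.DataFrame.from_dict(stats_rows, orient="index")


@dataclass
class PreprocessResult:
    """Outputs of the full preprocessing pass.

    ``raw_imputed`` keeps raw-scale (unnormalized) imputed concentrations for
    fold-change computation; ``normalized`` is the log2 + Pareto matrix used
    for clustering and ordination. Both exclude flagged outlier samples.
    """

    raw_imputed: pd.DataFrame
    normalized: pd.DataFrame
    report: PreprocessReport


def preprocess(matrix: pd.DataFrame, seed: int, *,
               missing_threshold: float = 0.30, r_threshold: float = 0.999,
               alpha: float = 0.05, outlier_subset: list[str] | None = None,
               ) -> PreprocessResult:
    """Full pipeline: filter → impute → log2+Pareto → drop correlates → outliers.

    ``outlier_subset`` restricts outlier detection (and removal) to the given
    sample ids — used to keep healthy controls out of the patient ordination.
    """
    filtered, excluded = filter_missingness(matrix, missing_threshold)
    n_missing = int(filtered.isna().sum().sum())
    imputed = impute_missing(filtered, seed)
    normalized = log2_pareto(imputed)
    normalized, dropped = drop_perfect_correlates(normalized, r_threshold)
    detect_on = (normalized.loc[outlier_subset] if outlier_subset is not None
                 else normalized)
    outlier_ids, outlier_stats = detect_outliers_pca(detect_on, alpha)
    keep = [s for s in normalized.index if s not in set(outlier_ids)]
    report = PreprocessReport(
        excluded_metabolites=excluded,
        dropped_correlates=dropped,
        n_imputed=n_missing,
        outliers={s: outlier_stats.loc[s].to_dict() for s in outlier_ids},
        params={"missing_threshold": missing_threshold,
                "r_threshold": r_threshold, "alpha": alpha, "seed": seed},
    )
    raw_kept = imputed.loc[keep]  # original column order, correlates retained
    return PreprocessResult(raw_imputed=raw_kept,
                            normalized=normalized.loc[keep],
                            report=report)
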