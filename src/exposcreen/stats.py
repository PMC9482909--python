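"""Feature-selection statistics for two-group metabolomics cohorts.

Mirrors the classic web-tool processing chain: IQR-based variance
filtering, normalization by sum, Pareto scaling, then univariate fold
change + Welch t-test and a supervised latent-variable model (NIPALS
PLS-DA, optionally with one orthogonal signal-correction component,
i.e. OPLS-DA with 1 predictive + 1 orthogonal component) yielding VIP
scores.  A feature is significant when it passes all three of: p < 0.1,
FC > 2 or FC < 0.5, and VIP > 1.  No multiple-testing correction is
applied by default (an FDR column is available behind a flag).

Conventions: fold changes are computed on sum-normalized but unscaled
intensities; t-tests and the PLS model use the Pareto-scaled matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .msdata import CohortDesign

__all__ = [
    "ProcessedMatrix",
    "SelectionResult",
    "iqr_filter",
    "normalize_and_scale",
    "univariate",
    "plsda_vip",
    "select_significant",
]

#: variance-filter ladder: (feature-count upper bound, fraction dropped)
IQR_LADDER = [(250, 0.0), (500, 0.05), (1000, 0.10), (2000, 0.25)]
IQR_TOP_FRACTION = 0.40


@dataclass
class ProcessedMatrix:
    """Feature x sample intensity matrix with a processing-stage tag."""

    data: pd.DataFrame  # index = feature_id, columns = sample_id
    stage: str  # raw | filtered | normalized | scaled
    design: CohortDesign

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.design.groups.get(s) == group]

    @property
    def non_qc_columns(self) -> list[str]:
        return [
            s for s in self.data.columns
            if self.design.groups.get(s) not in ("QC", "Blank")
        ]


@dataclass(frozen=True)
class SelectionResult:
    feature_id: str
    fold_change: float
    p_value: float
    vip: float
    significant: bool
    direction: str  # up_in_PD | up_in_Ctrl


def ladder_fraction(n_features: int) -> float:
    for bound, frac in IQR_LADDER:
        if n_features < bound:
            return frac
    return IQR_TOP_FRACTION


def iqr_filter(matrix: ProcessedMatrix, drop_fraction: float | None = None) -> ProcessedMatrix:
    """Drop the lowest-IQR fraction of features (IQR over non-QC samples).

    The fraction follows the feature-count ladder (0% below 250 features,
    5% below 500, 10% below 1000, 25% below 2000, else 40%) unless given
    explicitly.  Ties are broken by feature id for determinism; constant
    features (IQR 0) rank last and are dropped first.
    """
    df = matrix.data
    if len(df) < 10:
        raise ValueError("IQR filter needs >= 10 features")
    frac = ladder_fraction(len(df)) if drop_fraction is None else drop_fraction
    n_drop = int(len(df) * frac)
    if n_drop == 0:
        return ProcessedMatrix(df.copy(), "filtered", matrix.design)
    cols = matrix.non_qc_columns or list(df.columns)
    iqr = df[cols].quantile(0.75, axis=1) - df[cols].quantile(0.25, axis=1)
    order = sorted(df.index, key=lambda fid: (iqr[fid], fid))
    keep = set(order[n_drop:])
    return ProcessedMatrix(df.loc[[f for f in df.index if f in keep]], "filtered", matrix.design)


def normalize_and_scale(matrix: ProcessedMatrix) -> tuple[ProcessedMatrix, ProcessedMatrix]:
    """Sum-normalize each sample, then Pareto-scale each feature.

    Returns (normalized, scaled): each sample column of ``normalized`` sums
    to the mean raw total (so normalization is idempotent); ``scaled``
    centers each feature and divides by sqrt(SD), with constant features
    guarded to all-zero rows.  Fold changes are taken from ``normalized``,
    tests from ``scaled``.
    """
    df = matrix.data.astype(float)
    totals = df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    normalized = df / totals * totals.mean()
    sd = normalized.std(axis=1, ddof=1)
    centered = normalized.sub(normalized.mean(axis=1), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = centered.div(np.sqrt(sd), axis=0)
    scaled[sd == 0] = 0.0
    return (
        ProcessedMatrix(normalized, "normalized", matrix.design),
        ProcessedMatrix(scaled, "scaled", matrix.design),
    )


def univariate(
    normalized: ProcessedMatrix,
    scaled: ProcessedMatrix,
    group_a: str = "PD",
    group_b: str = "Ctrl",
) -> pd.DataFrame:
    """Per-feature fold change (group_a / group_b on normalized data) and
    two-sided Welch t-test p value (on scaled data).

    Features whose reference-group mean is zero have undefined FC and are
    excluded with a warning.
    """
    a_cols = normalized.group_columns(group_a)
    b_cols = normalized.group_columns(group_b)
    for g, cols in ((group_a, a_cols), (group_b, b_cols)):
        if len(cols) < 3:
            raise ValueError(f"group {g!r} has < 3 samples")
    mean_a = normalized.data[a_cols].mean(axis=1)
    mean_b = normalized.data[b_cols].mean(axis=1)
    undefined = mean_b == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} feature(s) with zero {group_b} mean excluded from FC",
            stacklevel=2,
        )
    fc = mean_a / mean_b.where(~undefined)
    t, p = sps.ttest_ind(
        scaled.data[a_cols], scaled.data[b_cols], axis=1, equal_var=False
    )
    out = pd.DataFrame(
        {"fold_change": fc, "p_value": p, "t_stat": t}, index=normalized.data.index
    )
    return out[~undefined]


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1.  X: samples x features (centered columns), y centered.

    Returns (weights W p x a, y-variance explained per component SSY_a).
    """
    Xa = X.copy()
    ya = y.astype(float).copy()
    p = X.shape[1]
    W = np.zeros((p, n_components))
    ssy = np.zeros(n_components)
    for a in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate (constant or orthogonal-to-class) matrix in PLS")
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError("degenerate score vector in PLS")
        p_load = Xa.T @ t / tt
        b = float(ya @ t) / tt
        W[:, a] = w
        ssy[a] = b * b * tt
        Xa = Xa - np.outer(t, p_load)
        ya = ya - b * t
    return W, ssy


def _remove_orthogonal_component(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One orthogonal-signal-correction component (Trygg-Wold O-PLS)."""
    w = X.T @ y
    w /= np.linalg.norm(w)
    t = X @ w
    p_load = X.T @ t / float(t @ t)
    w_orth = p_load - float(w @ p_load) * w
    norm = np.linalg.norm(w_orth)
    if norm == 0:
        return X  # no orthogonal variation to remove
    w_orth /= norm
    t_orth = X @ w_orth
    p_orth = X.T @ t_orth / float(t_orth @ t_orth)
    return X - np.outer(t_orth, p_orth)


def plsda_vip(
    scaled: ProcessedMatrix,
    group_a: str = "PD",
    group_b: str = "Ctrl",
    n_components: int = 1,
    orthogonal: bool = False,
) -> pd.Series:
    """VIP scores from a PLS-DA (optionally OPLS-DA) model.

    Class labels are coded -1/+1 and centered.  With ``orthogonal`` one
    orthogonal component is removed first and VIP is computed on the
    predictive component(s).  VIP_j = sqrt(p * sum_a w_ja^2 SSY_a /
    sum_a SSY_a), so sum_j VIP_j^2 = p (number of features).
    """
    a_cols = scaled.group_columns(group_a)
    b_cols = scaled.group_columns(group_b)
    cols = a_cols + b_cols
    n = len(cols)
    X = scaled.data[cols].T.to_numpy(dtype=float)  # samples x features
    y = np.array([1.0] * len(a_cols) + [-1.0] * len(b_cols))
    if n_components < 1 or n_components > min(n - 1, X.shape[1]):
        raise ValueError("n_components out of range")
    X = X - X.mean(axis=0)
    y = y - y.mean()
    if orthogonal:
        X = _remove_orthogonal_component(X, y)
    W, ssy = _nipals_pls1(X, y, n_components)
    p = X.shape[1]
    vip = np.sqrt(p * (W**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=scaled.data.index, name="vip")


def select_significant(
    uni: pd.DataFrame,
    vip: pd.Series,
    p_max: float = 0.1,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    vip_min: float = 1.0,
    fdr: bool = False,
) -> tuple[list[SelectionResult], pd.DataFrame]:
    """Apply the three-way conjunction: p below threshold AND extreme fold
    change AND VIP above threshold.

    Returns the per-feature results and a volcano table (log2 FC,
    -log10 p).  With ``fdr`` the p criterion uses Benjamini-Hochberg
    adjusted values instead (off by default).
    """
    idx = uni.index.intersection(vip.index)
    uni = uni.loc[idx]
    vip = vip.loc[idx]
    pvals = uni["p_value"]
    if fdr:
        from statsmodels.stats.multitest import multipletests

        pvals = pd.Series(
            multipletests(pvals.to_numpy(), method="fdr_bh")[1], index=pvals.index
        )
    results = []
    for fid in idx:
        fc = float(uni.at[fid, "fold_change"])
        p = float(pvals[fid])
        v = float(vip[fid])
        sig = (p < p_max) and (fc > fc_up or fc < fc_down) and (v > vip_min)
        results.append(
            SelectionResult(
                feature_id=fid,
                fold_change=fc,
                p_value=p,
                vip=v,
                significant=sig,
                direction="up_in_PD" if fc > 1 else "up_in_Ctrl",
            )
        )
    volcano = pd.DataFrame(
        {
            "log2_fc": np.log2(uni["fold_change"]),
            "neg_log10_p": -np.log10(uni["p_value"]),
        },
        index=idx,
    )
    return results, volcano
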