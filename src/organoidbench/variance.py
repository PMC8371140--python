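"""Gene filtering, PCA variance partitioning and PC–factor association.

The PCA follows the ``prcomp(center = TRUE, scale. = TRUE)`` convention:
genes are centered and unit-scaled across samples, components come from the
SVD of the samples × genes matrix, and per-gene contributions to a
component are the squared loadings expressed in percent. Association of a
component with a design factor is tested by Welch's two-tailed t-test for
two-level factors and a one-way ANOVA F-test for factors with three or
more levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FACTORS, SampleSheet

__all__ = [
    "filter_genes",
    "run_pca",
    "pc_factor_association",
    "contributing_genes",
    "PCAResult",
]


def filter_genes(
    normalized: pd.DataFrame,
    sheet: SampleSheet,
    iqr_threshold: float = 1.5,
    min_count: float = 10.0,
    min_conditions: int = 3,
    condition_factors: tuple = FACTORS,
) -> list:
    """Highly-variable, well-expressed gene filter.

    Keeps genes with (a) IQR of log2(normalized + 1) across samples above
    ``iqr_threshold`` and (b) mean normalized count above ``min_count`` in
    strictly more than ``min_conditions`` condition groups, a condition
    being one combination of the design factors (24 groups in the default
    2×3×2×2 design). The IQR is computed on the log scale because a raw-
    count variability filter is dominated by expression level.
    """
    if list(normalized.columns) != sheet.sample_ids:
        raise ValueError("normalized matrix columns do not match the sample sheet")
    logged = np.log2(normalized.to_numpy() + 1.0)
    q75, q25 = np.percentile(logged, [75, 25], axis=1)
    variable = (q75 - q25) > iqr_threshold

    keys = sheet.frame[list(condition_factors)].astype(str).agg("|".join, axis=1)
    cond_means = normalized.T.groupby(keys.to_numpy()).mean().T  # genes x conditions
    expressed = (cond_means.to_numpy() > min_count).sum(axis=1) > min_conditions

    keep = [g for g, ok in zip(normalized.index, variable & expressed) if ok]
    if not keep:
        raise ValueError(
            "gene filter removed everything; relax iqr_threshold / min_count"
        )
    return keep


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: pd.Series  # per component, sums to 1
    contribution: pd.DataFrame  # genes x components, percent, sums to 100

    @property
    def components(self) -> list:
        return list(self.scores.columns)


def run_pca(matrix: pd.DataFrame, log: bool = True) -> PCAResult:
    """PCA of a genes × samples matrix (restricted to filtered genes).

    Genes are centered and unit-scaled across samples (ddof = 1); the
    samples × genes matrix is decomposed by SVD. ``log`` first transforms
    to log2(x + 1), the default scale for expression PCA here. Zero-
    variance genes are dropped with a warning. Sign convention: within each
    component the gene with the largest |loading| has a positive loading.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    if log:
        x = np.log2(x + 1.0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance gene(s) before PCA")
        x = x[:, keep]
        sd = sd[keep]
    genes = [g for g, k in zip(matrix.index, keep) if k]
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    x = (x - x.mean(axis=0)) / sd
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_comp = min(n - 1, x.shape[1])
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    eigvals = s**2 / (n - 1)
    total_var = x.shape[1]  # each scaled gene contributes unit variance
    # fractions over all computable components sum to 1 because the scaled
    # matrix has rank <= n - 1 (total variance = number of scaled genes)
    fractions = eigvals / total_var
    loadings = vt.T  # genes x comp, unit columns
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_comp)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = u * s * flip
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    contribution = 100.0 * loadings**2 / (loadings**2).sum(axis=0, keepdims=True)
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=genes, columns=comp_names),
        variance_fraction=pd.Series(fractions, index=comp_names),
        contribution=pd.DataFrame(contribution, index=genes, columns=comp_names),
    )


def pc_factor_association(
    pca: PCAResult, sheet: SampleSheet, component: str, factor: str
) -> float:
    """p-value of the association between one PC and one design factor.

    Welch's two-tailed t-test for two-level factors; one-way ANOVA F-test
    for three or more levels.
    """
    if component not in pca.scores.columns:
        raise KeyError(f"unknown component {component!r}")
    scores = pca.scores[component]
    if list(pca.scores.index) != sheet.sample_ids:
        raise ValueError("PCA scores do not match the sample sheet")
    levels = sheet.levels(factor)
    groups = [scores.to_numpy()[sheet.mask(**{factor: lvl})] for lvl in levels]
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 observed levels")
    small = [lvl for lvl, g in zip(levels, groups) if len(g) < 2]
    if small:
        raise ValueError(f"factor {factor!r}: levels with <2 samples: {small}")
    if len(groups) == 2:
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        if np.isnan(p):  # zero variance in both groups with equal means
            p = 1.0
        return float(p)
    _, p = stats.f_oneway(*groups)
    return float(p)


def contributing_genes(
    pca: PCAResult,
    component: str,
    cutoff_log2: float = -3.32,
    mode: str = "fixed",
) -> pd.Series:
    """Highly-contributing genes of one component, sorted descending.

    ``mode='fixed'`` keeps genes with log2(contribution in percent) at or
    above ``cutoff_log2`` (the default −3.32 corresponds to ≈0.1%).
    ``mode='knee'`` instead places the cutoff at the knee of the sorted
    log2-contribution curve (maximum distance to the chord), a density-
    based alternative for when no fixed cutoff is wanted.
    """
    if component not in pca.contribution.columns:
        raise KeyError(f"unknown component {component!r}")
    contrib = pca.contribution[component].sort_values(ascending=False)
    positive = contrib[contrib > 0]
    logc = np.log2(positive.to_numpy())
    if mode == "fixed":
        selected = positive[logc >= cutoff_log2]
    elif mode == "knee":
        if len(positive) < 3:
            selected = positive
        else:
            x = np.arange(len(logc), dtype=float)
            chord = logc[0] + (logc[-1] - logc[0]) * x / x[-1]
            knee = int(np.argmax(chord - logc))
            selected = positive.iloc[: max(knee, 1)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return selected
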