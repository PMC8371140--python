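"""Size-factor normalization and a per-gene negative-binomial Wald test.

The normalization is the standard median-of-ratios scheme: each sample's
size factor is the median, over genes with no zero count, of that sample's
counts divided by the gene's geometric mean across samples.

The differential-expression test is a deliberately simple NB Wald test on
the log ratio of size-factor-normalized group means: per-gene dispersion is
estimated by method of moments and shrunk 50% toward a fitted
``a0 + a1/mu`` mean-dispersion trend, the variance of each log group mean
follows from the NB variance function by the delta method, and the Wald
statistic is referred to the standard normal. It is not a reimplementation
of any published DE engine — no outlier replacement, no independent
filtering — but it is calibrated under the null and consumes/produces the
same quantities (log2FC, p, adjusted p) the downstream analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SampleSheet

__all__ = [
    "size_factors",
    "normalize",
    "normalized_frame",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "Contrast",
]

LN2 = np.log(2.0)
_LFC_PSEUDOCOUNT = 0.5  # added to normalized group means before taking the ratio


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, one positive scalar per sample.

    Genes with a zero count in any sample are excluded from the median.
    """
    mat = counts.counts.astype(float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios is "
            "undefined (consider a pseudo-reference fallback)"
        )
    logs = np.log(mat[usable])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return factors


def normalize(counts: CountMatrix, factors: np.ndarray) -> np.ndarray:
    """Divide each sample's counts by its size factor (preserves zeros)."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,):
        raise ValueError("one size factor per sample required")
    if (factors <= 0).any():
        raise ValueError("size factors must be strictly positive")
    return counts.counts / factors[None, :]


def normalized_frame(counts: CountMatrix, factors: np.ndarray | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return pd.DataFrame(
        normalize(counts, factors), index=counts.gene_ids, columns=counts.sample_ids
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone in rank, capped at 1).

    NaN entries (untested genes) are passed through untouched.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def estimate_dispersion(
    normalized: np.ndarray,
    size_f: np.ndarray,
    groups: list[np.ndarray],
    floor: float = 1e-8,
    trend_shrinkage: float = 0.5,
) -> np.ndarray:
    """Per-gene NB dispersion by method of moments with trend shrinkage.

    With y = count/s and Var(count) = mu + alpha mu^2, the within-group
    pooled variance of y satisfies E[S2] ≈ q * mean(1/s) + alpha q^2, which
    is solved for alpha gene by gene (floored). A parametric trend
    alpha(q) = a0 + a1/q is fitted across genes and each raw estimate is
    shrunk ``trend_shrinkage`` of the way toward it.
    """
    inv_s = float(np.mean(1.0 / size_f))
    n = sum(len(g) for g in groups)
    dof = n - len(groups)
    if dof < 1:
        raise ValueError("need at least one residual degree of freedom")
    ss = np.zeros(normalized.shape[0])
    for g in groups:
        block = normalized[:, g]
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / dof
    q = normalized.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - q * inv_s) / q**2
    raw = np.where(np.isfinite(raw), raw, floor)
    raw = np.maximum(raw, floor)
    # trend fit on informative genes (positive mean, alpha above the floor)
    ok = (q > 0) & (raw > floor * 10)
    if ok.sum() >= 10:
        x = np.column_stack([np.ones(ok.sum()), 1.0 / q[ok]])
        coef, *_ = np.linalg.lstsq(x, raw[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a0, a1 = float(np.median(raw)), 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(q > 0, q, np.inf)
    alpha = (1 - trend_shrinkage) * raw + trend_shrinkage * trend
    return np.maximum(alpha, floor)


@dataclass(frozen=True)
class Contrast:
    """A two-level contrast: ``level_b`` vs reference ``level_a`` for ``factor``,
    optionally restricted to a stratum of other factor levels."""

    factor: str
    level_b: str
    level_a: str
    stratum: tuple = ()

    @property
    def label(self) -> str:
        parts = [f"{self.factor}:{self.level_b}_vs_{self.level_a}"]
        parts += [f"{f}={l}" for f, l in self.stratum]
        return "|".join(parts)


def nb_wald_test(
    counts: CountMatrix,
    sheet: SampleSheet,
    contrast: Contrast,
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``contrast.level_b`` vs ``contrast.level_a``.

    Returns a DEG table with columns baseMean, log2FoldChange, lfcSE, stat,
    pvalue, padj and a ``tested`` flag; all-zero genes are flagged untested
    (NaN statistics) rather than dropped. BH adjustment is applied within
    the contrast over tested genes.
    """
    if not sheet.matches(counts):
        raise ValueError("sample sheet does not match the count matrix")
    stratum = dict(contrast.stratum)
    base_mask = sheet.mask(**stratum) if stratum else np.ones(len(sheet), dtype=bool)
    mask_a = base_mask & sheet.mask(**{contrast.factor: contrast.level_a})
    mask_b = base_mask & sheet.mask(**{contrast.factor: contrast.level_b})
    idx_a, idx_b = np.flatnonzero(mask_a), np.flatnonzero(mask_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(
            f"contrast {contrast.label!r}: both groups need >=2 samples "
            f"(got {len(idx_a)} vs {len(idx_b)})"
        )
    sel = np.concatenate([idx_a, idx_b])
    sub = CountMatrix(
        counts.gene_ids,
        [counts.sample_ids[i] for i in sel],
        counts.counts[:, sel],
    )
    if factors is None:
        sf = size_factors(sub)
    else:
        sf = np.asarray(factors, dtype=float)[sel]
    y = normalize(sub, sf)
    na = len(idx_a)
    ya, yb = y[:, :na], y[:, na:]
    sa, sb = sf[:na], sf[na:]
    mean_a, mean_b = ya.mean(axis=1), yb.mean(axis=1)
    base_mean = y.mean(axis=1)
    alpha = estimate_dispersion(y, sf, [np.arange(na), np.arange(na, len(sel))])

    c = _LFC_PSEUDOCOUNT
    qa, qb = mean_a + c, mean_b + c
    log2fc = np.log2(qb / qa)
    # delta method: Var(log mean) = Var(mean) / mean^2 with NB variance
    var_a = (qa * np.mean(1.0 / sa) + alpha * qa**2) / len(sa)
    var_b = (qb * np.mean(1.0 / sb) + alpha * qb**2) / len(sb)
    se_ln = np.sqrt(var_a / qa**2 + var_b / qb**2)
    lfc_se = se_ln / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.log(qb / qa) / se_ln
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))

    tested = sub.counts.sum(axis=1) > 0
    log2fc = np.where(tested, log2fc, np.nan)
    stat = np.where(tested, stat, np.nan)
    pvalue = np.where(tested, pvalue, np.nan)
    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "lfcSE": np.where(tested, lfc_se, np.nan),
            "stat": stat,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "tested": tested,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    table.attrs["contrast"] = contrast.label
    return table


def standard_contrasts(sample_type: str | None = None) -> list[Contrast]:
    """The study's per-feature contrasts, optionally within one sample type.

    Compartment is oriented aboral vs oral (oral is the reference);
    intermediate samples enter only composition/ANOVA analyses.
    """
    stratum = (("sample_type", sample_type),) if sample_type else ()
    return [
        Contrast("compartment", "aboral", "oral", stratum),
        Contrast("gender", "female", "male", stratum),
        Contrast("age", "old", "young", stratum),
    ]
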