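"""DEG matrices and linear-model effect sizes for feature retention.

A DEG matrix holds, per gene and per contrast, the log2 fold-change when
the gene passes the significance rule for that contrast and exactly 0
otherwise. Effect sizes are adjusted coefficients of determination of
ordinary least-squares models over genes: regressing an in-vivo feature's
log2FC vector on the in-vitro one quantifies how much of the feature
survives culture, and regressing aging log2FCs on compartment/gender
stratum indicators quantifies how much those variables modify aging.
Model quality is assessed by the F-test of the full regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DEGMatrix",
    "EffectSizeResult",
    "build_deg_matrix",
    "effect_size",
    "feature_retention",
    "aging_modifiers",
    "deg_overlap",
]


@dataclass
class DEGMatrix:
    """Genes × contrasts log2FC matrix; zeros mean 'not significant here'."""

    values: pd.DataFrame
    rule: str  # "padj" or "pvalue"
    alpha: float

    @property
    def empty(self) -> bool:
        return self.values.empty

    def column(self, label: str) -> pd.Series:
        if label not in self.values.columns:
            raise KeyError(f"no contrast {label!r} in DEG matrix")
        return self.values[label]

    def gene_sets(self) -> dict:
        """Significant-gene set per contrast (the nonzero entries)."""
        return {
            c: set(self.values.index[self.values[c] != 0]) for c in self.values.columns
        }


def build_deg_matrix(
    tables: dict, rule: str = "padj", alpha: float = 0.05
) -> DEGMatrix:
    """Assemble a DEG matrix from per-contrast DEG tables.

    ``tables`` maps a contrast label to a DEG table (index gene, columns
    including log2FoldChange and the rule column). A gene enters the matrix
    if it passes ``rule < alpha`` in at least one contrast; entries where
    it does not pass are exactly 0. Genes significant nowhere are dropped.
    """
    if rule not in ("padj", "pvalue"):
        raise ValueError("rule must be 'padj' or 'pvalue'")
    cols = {}
    for label, table in tables.items():
        if table.index.has_duplicates:
            dup = table.index[table.index.duplicated()][0]
            raise ValueError(f"contrast {label!r}: duplicate gene entry {dup!r}")
        passing = (table[rule] < alpha) & np.isfinite(table["log2FoldChange"])
        cols[label] = table["log2FoldChange"].where(passing, 0.0)
    values = pd.DataFrame(cols).fillna(0.0)
    values = values.loc[(values != 0).any(axis=1)]
    return DEGMatrix(values=values, rule=rule, alpha=alpha)


@dataclass
class EffectSizeResult:
    outcome: str
    predictors: list
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    n_genes: int

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictors": list(self.predictors),
            "adj_r_squared": self.adj_r_squared,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "n_genes": self.n_genes,
        }


def effect_size(outcome: pd.Series, predictors: pd.DataFrame) -> EffectSizeResult:
    """Adjusted R² and F-test of an OLS fit of ``outcome`` on ``predictors``.

    Adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1) with an intercept always
    included. Constant outcomes and collinear predictor pairs are rejected.
    """
    predictors = pd.DataFrame(predictors)
    common = outcome.index.intersection(predictors.index)
    y = outcome.loc[common].to_numpy(dtype=float)
    x = predictors.loc[common].to_numpy(dtype=float)
    n, k = x.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} genes for {k} predictor(s), got {n}")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; effect size undefined")
    for a, b in combinations(range(k), 2):
        xa, xb = x[:, a], x[:, b]
        if np.ptp(xa) > 0 and np.ptp(xb) > 0:
            if abs(np.corrcoef(xa, xb)[0, 1]) > 1 - 1e-12:
                raise ValueError(
                    f"collinear predictors: {predictors.columns[a]!r} and "
                    f"{predictors.columns[b]!r}"
                )
    model = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    return EffectSizeResult(
        outcome=str(outcome.name),
        predictors=[str(c) for c in predictors.columns],
        adj_r_squared=float(model.rsquared_adj),
        f_statistic=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        n_genes=int(n),
    )


def _align(vivo: DEGMatrix, vitro: DEGMatrix):
    """Outer-join the two matrices on genes, filling zeros."""
    genes = vivo.values.index.union(vitro.values.index)
    return (
        vivo.values.reindex(genes, fill_value=0.0),
        vitro.values.reindex(genes, fill_value=0.0),
    )


def feature_retention(
    vivo: DEGMatrix,
    vitro: DEGMatrix,
    features: tuple = ("compartment", "gender", "age"),
    drop_all_zero: bool = True,
) -> dict:
    """How much of each in-vivo feature the in-vitro system retains.

    For every feature, fits the in-vivo log2FC vector on (i) the matching
    in-vitro vector (simple model) and (ii) all in-vitro feature vectors
    together (combined model); returns ``{feature: {"simple": ...,
    "combined": ...}}`` of :class:`EffectSizeResult`.

    ``drop_all_zero`` removes genes that are zero in every column used by a
    model before fitting; all-zero rows carry no information and only
    deflate R². Set it to False to keep the full gene union.
    """
    for f in features:
        for mat, side in ((vivo, "in-vivo"), (vitro, "in-vitro")):
            if f not in mat.values.columns:
                raise KeyError(f"feature {f!r} missing from the {side} DEG matrix")
    v_vivo, v_vitro = _align(vivo, vitro)
    out: dict = {}
    for f in features:
        y_all = v_vivo[f]
        x_simple = v_vitro[[f]]
        x_comb = v_vitro[list(features)]
        if drop_all_zero:
            keep_s = (y_all != 0) | (x_simple != 0).any(axis=1)
            keep_c = (y_all != 0) | (x_comb != 0).any(axis=1)
        else:
            keep_s = keep_c = pd.Series(True, index=y_all.index)
        y_s = y_all[keep_s].rename(f"in_vivo_{f}")
        y_c = y_all[keep_c].rename(f"in_vivo_{f}")
        out[f] = {
            "simple": effect_size(y_s, x_simple.loc[keep_s].add_prefix("in_vitro_")),
            "combined": effect_size(y_c, x_comb.loc[keep_c].add_prefix("in_vitro_")),
        }
    return out


def aging_modifiers(
    aging: DEGMatrix, strata: pd.DataFrame, drop_all_zero: bool = True
) -> dict:
    """Effect of compartment, gender and both on aging log2FCs.

    ``aging`` holds one column per young-vs-old contrast computed within a
    stratum; ``strata`` maps each column label to its ``compartment`` and
    ``gender``. The matrix is stacked to long form (one row per gene ×
    stratum) and the aging log2FC is regressed on compartment indicators,
    gender indicators, and both; adjusted R² and F-test per model.
    """
    needed = {"compartment", "gender"}
    if not needed.issubset(strata.columns):
        raise ValueError("strata table must have 'compartment' and 'gender' columns")
    missing = [c for c in aging.values.columns if c not in strata.index]
    if missing:
        raise ValueError(f"strata metadata missing for contrasts: {missing}")
    long = aging.values.stack().rename("log2fc").reset_index()
    long.columns = ["gene", "contrast", "log2fc"]
    long["compartment"] = long["contrast"].map(strata["compartment"])
    long["gender"] = long["contrast"].map(strata["gender"])
    if drop_all_zero:
        nonzero_genes = aging.values.index[(aging.values != 0).any(axis=1)]
        long = long[long["gene"].isin(set(nonzero_genes))]
    y = long["log2fc"]
    y.index = pd.RangeIndex(len(y))
    y = y.rename("aging_log2fc")
    dummies = {
        "compartment": pd.get_dummies(long["compartment"], prefix="compartment", drop_first=True, dtype=float),
        "gender": pd.get_dummies(long["gender"], prefix="gender", drop_first=True, dtype=float),
    }
    for d in dummies.values():
        d.index = pd.RangeIndex(len(d))
    results = {
        "compartment": effect_size(y, dummies["compartment"]),
        "gender": effect_size(y, dummies["gender"]),
        "compartment+gender": effect_size(
            y, pd.concat([dummies["compartment"], dummies["gender"]], axis=1)
        ),
    }
    return results


def deg_overlap(sets: dict) -> pd.DataFrame:
    """Pairwise and full intersection/difference cardinalities of DEG sets."""
    names = list(sets)
    rows = []
    for a, b in combinations(names, 2):
        sa, sb = set(sets[a]), set(sets[b])
        inter = len(sa & sb)
        union = len(sa | sb)
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "size_a": len(sa),
                "size_b": len(sb),
                "intersection": inter,
                "only_a": len(sa - sb),
                "only_b": len(sb - sa),
                "jaccard": inter / union if union else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["full_intersection"] = (
        len(set.intersection(*(set(s) for s in sets.values()))) if sets else 0
    )
    return table
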