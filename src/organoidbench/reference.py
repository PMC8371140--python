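"""Single-cell normalization, clustering, marker definition and signatures.

The workflow mirrors standard droplet-data practice at a reduced scale:
cells are depth-normalized to the median per-cell total and log10-
transformed, clustered by k-means on the top principal components, each
cluster is assigned a cell type by marker-set expression, per-cluster
markers are defined by a fold-change + adjusted-p rule (log2FC >= 2 and
BH-adjusted p < 0.05), and the signature matrix used for deconvolution is
built from mean normalized (linear-scale) expression of the marker union —
deconvolution mixes linearly, so the signature must live on the linear
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .de import bh_adjust
from .io import CellCounts, GeneSet

__all__ = [
    "NormalizedCells",
    "SignatureMatrix",
    "normalize_cells",
    "cluster_cells",
    "recluster",
    "assign_cell_types",
    "define_markers",
    "build_signature",
]


@dataclass
class NormalizedCells:
    """Depth-normalized single-cell matrices (cells × genes).

    ``linear`` holds counts scaled so every cell totals the median per-cell
    depth; ``log`` is log10(linear + 1). ``n_dropped`` counts zero-total
    cells removed on the way in.
    """

    linear: pd.DataFrame
    log: pd.DataFrame
    n_dropped: int = 0

    @property
    def cell_ids(self) -> list:
        return list(self.linear.index)


@dataclass
class SignatureMatrix:
    """Marker-gene × cell-type reference expression on the linear scale."""

    profiles: pd.DataFrame  # markers x cell types
    markers_per_type: dict  # cell type -> list of its own markers

    def __post_init__(self) -> None:
        if self.profiles.index.has_duplicates:
            dup = self.profiles.index[self.profiles.index.duplicated()][0]
            raise ValueError(f"duplicate marker row {dup!r} in signature")
        owned = {g for gs in self.markers_per_type.values() for g in gs}
        orphan = [g for g in self.profiles.index if g not in owned]
        if orphan:
            raise ValueError(f"signature rows not in any marker set: {orphan[:5]}")
        zero = self.profiles.index[(self.profiles == 0).all(axis=1)]
        if len(zero):
            raise ValueError(f"all-zero marker rows in signature: {list(zero[:5])}")

    @property
    def cell_types(self) -> list:
        return list(self.profiles.columns)

    @property
    def genes(self) -> list:
        return list(self.profiles.index)


def normalize_cells(cells: CellCounts) -> NormalizedCells:
    """Scale every cell's total to the median per-cell total; log10(x + 1).

    Genes expressed in no cell are removed first; zero-total cells are
    dropped (counted in ``n_dropped``).
    """
    frame = cells.to_frame()
    frame = frame.loc[:, frame.sum(axis=0) > 0]
    totals = frame.sum(axis=1)
    dropped = int((totals == 0).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} zero-total cell(s)")
        frame = frame.loc[totals > 0]
        totals = totals[totals > 0]
    if frame.empty:
        raise ValueError("no cells with nonzero totals")
    median_total = float(np.median(totals.to_numpy()))
    linear = frame.div(totals, axis=0) * median_total
    return NormalizedCells(linear=linear, log=np.log10(linear + 1.0), n_dropped=dropped)


def _cell_pcs(log_frame: pd.DataFrame, n_pcs: int) -> np.ndarray:
    x = log_frame.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    n_pcs = min(n_pcs, min(x.shape) - 1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def cluster_cells(
    normalized: NormalizedCells,
    k: int = 9,
    n_starts: int = 10,
    seed: int = 0,
    n_pcs: int = 20,
) -> np.ndarray:
    """Best-of-``n_starts`` k-means labels on the top PCs of the log matrix."""
    n_cells = normalized.log.shape[0]
    if k > n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({n_cells})")
    pcs = _cell_pcs(normalized.log, n_pcs)
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=int(seed))
    return km.fit_predict(pcs)


def recluster(
    normalized: NormalizedCells,
    labels: np.ndarray,
    target: int,
    k: int = 2,
    n_starts: int = 10,
    seed: int = 0,
    n_pcs: int = 20,
) -> np.ndarray:
    """Split one cluster into ``k`` subclusters (targeted re-clustering).

    New labels continue after the current maximum so no existing cluster id
    is reused.
    """
    labels = np.asarray(labels).copy()
    member = labels == target
    if member.sum() < k:
        raise ValueError(f"cluster {target} has fewer than k={k} cells")
    sub = NormalizedCells(
        linear=normalized.linear.loc[member], log=normalized.log.loc[member]
    )
    sub_labels = cluster_cells(sub, k=k, n_starts=n_starts, seed=seed, n_pcs=n_pcs)
    base = labels.max() + 1
    labels[member] = base + sub_labels
    return labels


def assign_cell_types(
    labels: np.ndarray,
    marker_sets: list[GeneSet],
    normalized: NormalizedCells,
    tie_tol: float = 1e-9,
) -> pd.DataFrame:
    """Type each cluster by its highest mean z-scored marker-set expression.

    Returns a table with the winning type, its score, the runner-up margin,
    and a status flag: ``ok``, ``ambiguous`` (tie within ``tie_tol``) or
    ``unassigned`` (no marker set expressed in the cluster at all).
    """
    log = normalized.log
    sd = log.std(axis=0, ddof=0)
    expressed = sd > 0
    z = (log.loc[:, expressed] - log.loc[:, expressed].mean(axis=0)) / sd[expressed]
    rows = []
    for cluster in np.unique(labels):
        mask = labels == cluster
        scores = {}
        any_expression = False
        for gs in marker_sets:
            present = [g for g in gs.genes if g in z.columns]
            if present and normalized.linear.loc[mask, [g for g in gs.genes if g in normalized.linear.columns]].to_numpy().sum() > 0:
                any_expression = True
            scores[gs.name] = (
                float(z.loc[mask, present].to_numpy().mean()) if present else -np.inf
            )
        ranked = sorted(scores.items(), key=lambda kv: kv[1], reverse=True)
        best, second = ranked[0], ranked[1] if len(ranked) > 1 else (None, -np.inf)
        margin = best[1] - second[1]
        if not any_expression:
            status, assigned = "unassigned", None
        elif margin <= tie_tol:
            status, assigned = "ambiguous", None
        else:
            status, assigned = "ok", best[0]
        rows.append(
            {
                "cluster": int(cluster),
                "cell_type": assigned,
                "score": best[1],
                "runner_up_margin": margin,
                "status": status,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def define_markers(
    normalized: NormalizedCells,
    labels: np.ndarray,
    target,
    log2fc_min: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Markers of one cluster vs all other cells.

    Per gene: log2 fold change of (mean linear expression + pseudocount)
    in the target cluster vs the rest, and a two-sided Welch t-test on the
    log-normalized values; BH adjustment across genes. Genes pass with
    log2FC >= ``log2fc_min`` AND adjusted p < ``alpha``.
    """
    labels = np.asarray(labels)
    in_mask = labels == target
    if in_mask.sum() < 3:
        raise ValueError(f"cluster {target!r} has fewer than 3 cells")
    lin, log = normalized.linear.to_numpy(), normalized.log.to_numpy()
    mean_in = lin[in_mask].mean(axis=0)
    mean_out = lin[~in_mask].mean(axis=0)
    log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(log[in_mask], log[~in_mask], equal_var=False, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    padj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2FoldChange": log2fc,
            "pvalue": p,
            "padj": padj,
            "selected": (log2fc >= log2fc_min) & (padj < alpha),
        },
        index=normalized.linear.columns,
    )
    return table.sort_values("log2FoldChange", ascending=False)


def build_signature(
    normalized: NormalizedCells,
    type_labels,
    markers_per_type: dict,
    type_order: tuple | None = None,
) -> SignatureMatrix:
    """Mean linear-scale expression of each marker per cell type.

    ``type_labels`` gives the cell type of every cell (after cluster
    assignment); rows are the union of the per-type marker lists in the
    given order, columns follow ``type_order`` (default: marker-dict
    order).
    """
    type_labels = np.asarray(type_labels)
    if type_order is None:
        type_order = tuple(markers_per_type)
    union: list = []
    seen = set()
    for ctype, genes in markers_per_type.items():
        if not genes:
            raise ValueError(f"marker list for {ctype!r} is empty")
        for g in genes:
            if g in seen:
                continue
            seen.add(g)
            union.append(g)
    missing = [g for g in union if g not in normalized.linear.columns]
    if missing:
        raise ValueError(f"marker gene(s) absent from the matrix: {missing[:5]}")
    cols = {}
    for ctype in type_order:
        mask = type_labels == ctype
        if not mask.any():
            raise ValueError(f"no cells labelled {ctype!r}")
        cols[ctype] = normalized.linear.loc[mask, union].mean(axis=0)
    profiles = pd.DataFrame(cols)[list(type_order)]
    profiles.index = pd.Index(union, name="gene_id")
    return SignatureMatrix(profiles=profiles, markers_per_type=dict(markers_per_type))
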