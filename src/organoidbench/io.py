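"""Readers, writers and validated containers for the pipeline's on-disk formats.

Orientation conventions, enforced by the container classes:

* bulk count matrices are genes-as-rows (``CountMatrix``), mirroring the
  TSV layout produced by read-counting tools;
* single-cell matrices are cells-as-rows (``CellCounts``), mirroring the
  droplet-ecosystem convention (barcodes index rows).

All parsers reject malformed input instead of coercing it, and error
messages carry the file and the offending row/column or line number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

#: Factor columns every sample sheet must carry, in canonical order.
FACTORS = ("sample_type", "compartment", "gender", "age")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


def _check_unique(ids, kind: str, context: str = "") -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} ID {i!r}{context}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Genes × samples matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())


@dataclass
class CellCounts:
    """Cells × genes matrix of non-negative integer counts (single-cell)."""

    cell_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.counts = np.asarray(self.counts)
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"cell matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if (self.counts < 0).any():
            raise FormatError("negative single-cell count")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class SampleSheet:
    """Per-sample factor levels for the factorial design."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        # reduced designs may drop canonical factors, but a sheet with no
        # factor column at all cannot drive any contrast
        missing = [c for c in ("sample_id", "replicate") if c not in self.frame.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if not self.factors:
            raise FormatError("sample sheet has no factor columns")
        _check_unique(list(self.frame["sample_id"]), "sample")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def factors(self) -> list:
        return [c for c in self.frame.columns if c not in ("sample_id", "replicate")]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def __len__(self) -> int:
        return len(self.frame)

    def levels(self, factor: str) -> list[str]:
        if factor not in self.frame.columns:
            raise KeyError(f"unknown factor {factor!r}")
        return list(pd.unique(self.frame[factor]))

    def mask(self, **levels: str) -> np.ndarray:
        """Boolean mask of samples matching all given factor=level pairs."""
        m = np.ones(len(self.frame), dtype=bool)
        for factor, level in levels.items():
            m &= (self.frame[factor] == level).to_numpy()
        return m

    def matches(self, counts: CountMatrix) -> bool:
        return self.sample_ids == counts.sample_ids


@dataclass
class GeneSet:
    """A named gene set, optionally with per-gene direction (+1 / -1)."""

    name: str
    genes: tuple
    directions: dict | None = field(default=None)

    def __post_init__(self) -> None:
        self.genes = tuple(str(g) for g in self.genes)
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, "gene", f" in set {self.name!r}")
        if self.directions is not None:
            missing = [g for g in self.genes if g not in self.directions]
            if missing:
                raise FormatError(
                    f"gene set {self.name!r}: directions missing for {missing[:5]}"
                )
            bad = {d for d in self.directions.values()} - {1, -1}
            if bad:
                raise FormatError(f"gene set {self.name!r}: directions must be +1/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# bulk counts TSV


def read_counts(path, rrna_prefixes: tuple = ()) -> CountMatrix:
    """Read a genes-as-rows count TSV (first column gene IDs, header sample IDs).

    ``rrna_prefixes`` optionally drops ribosomal-RNA genes on load by ID
    prefix; the study removes rRNA genes before any analysis but does not
    publish the gene list, so the filter is caller-supplied.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header has no sample columns")
        sample_ids = header[1:]
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {len(header)}"
                )
            gene = parts[0]
            try:
                vals = [int(v) for v in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno} (gene {gene!r}): {exc}") from exc
            if any(v < 0 for v in vals):
                raise FormatError(f"{path}: line {lineno} (gene {gene!r}): negative count")
            genes.append(gene)
            rows.append(vals)
    try:
        matrix = CountMatrix(genes, sample_ids, np.array(rows, dtype=np.int64))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if rrna_prefixes:
        keep = [
            i
            for i, g in enumerate(matrix.gene_ids)
            if not any(g.startswith(p) for p in rrna_prefixes)
        ]
        matrix = CountMatrix(
            [matrix.gene_ids[i] for i in keep], matrix.sample_ids, matrix.counts[keep]
        )
    return matrix


def write_counts(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "replicate" in frame.columns:
        frame["replicate"] = frame["replicate"].astype(int)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> list:
    """Parse a GMT file: one set per line, name <tab> description <tab> members."""
    path = Path(path)
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >=3 fields, got {len(parts)}"
                )
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            try:
                sets.append(GeneSet(name, tuple(members)))
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return sets


def write_gmt(sets, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# MatrixMarket triplet (single cell)


def read_mtx(directory) -> CellCounts:
    """Read an MTX triplet directory (matrix.mtx genes×cells, features/barcodes TSV)."""
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    genes = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if dense.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{directory}: matrix.mtx shape {dense.shape} does not match "
            f"{len(genes)} features x {len(cells)} barcodes"
        )
    if not np.all(np.equal(np.mod(dense, 1), 0)):
        raise FormatError(f"{directory}: matrix.mtx has non-integer entries")
    return CellCounts(list(cells), list(genes), dense.astype(np.int64).T)


def write_mtx(cells: CellCounts, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(cells.counts.T)  # genes x cells on disk
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse)
    pd.Series(cells.gene_ids).to_csv(directory / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(cells.cell_ids).to_csv(directory / "barcodes.tsv", sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# JSON / YAML helpers


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg
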