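"""Readers and writers for the external formats the pipeline touches.

Count matrices travel as TSV (first column = gene id, header row = sample
ids) or as MatrixMarket coordinate files with plain-text row/column id
sidecars. Gene sets come in as GMT, gene-level statistics as two-column
TSV. Everything is validated on the way in: counts must be non-negative
integers, identifiers must be unique, and gene-set members are
deduplicated. Gene identifiers are opaque strings throughout; species
prefixes such as ``hs:`` / ``mm:`` are preserved but never required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "SampleTable",
    "GeneSetCollection",
    "GeneAnnotation",
    "read_count_matrix",
    "write_count_matrix",
    "read_count_matrix_mtx",
    "write_count_matrix_mtx",
    "read_sample_table",
    "write_sample_table",
    "read_gmt",
    "write_gmt",
    "read_gene_stats",
    "write_gene_stats",
    "read_gene_annotation",
    "write_gene_annotation",
]

CONDITIONS = ("monoculture", "coculture", "sandwich", "glia_mono")


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)
    return ids


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix tagged with species and alignment reference.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered unique identifiers for rows and columns.
    counts
        Non-negative integer array, shape ``(n_genes, n_samples)``.
    species
        ``"human"`` or ``"mouse"``.
    alignment_ref
        ``"single"`` (species' own genome only) or ``"mixed"``
        (combined two-species reference).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    species: str = "human"
    alignment_ref: str = "single"

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and np.isnan(counts.astype(float)).any():
            raise ValueError("NaN entry in count matrix")
        if counts.size and (counts < 0).any():
            raise ValueError("negative count in matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts.astype(float))
            if counts.size and np.abs(counts - rounded).max() > 1e-8:
                raise ValueError("non-integer count in matrix")
            counts = rounded.astype(np.int64)
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)
        if self.species not in ("human", "mouse"):
            raise ValueError(f"species must be 'human' or 'mouse', got {self.species!r}")
        if self.alignment_ref not in ("single", "mixed"):
            raise ValueError(f"alignment_ref must be 'single' or 'mixed', got {self.alignment_ref!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        keep = list(gene_ids)
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in keep if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in keep]
        return CountMatrix(keep, list(self.sample_ids), self.counts[rows, :],
                           self.species, self.alignment_ref)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        keep = list(sample_ids)
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in keep]
        return CountMatrix(list(self.gene_ids), keep, self.counts[:, cols],
                           self.species, self.alignment_ref)


@dataclass
class SampleTable:
    """Per-sample metadata: condition, donor, replicate group, batch, timepoint, Ngn2."""

    frame: pd.DataFrame

    REQUIRED = ("condition", "donor", "replicate_group", "batch", "timepoint")

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df = df.copy()
                df.index.name = "sample_id"
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"sample table missing column {col!r}")
        bad = set(df["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition value(s): {sorted(bad)}")
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def condition(self) -> pd.Series:
        return self.frame["condition"]

    def ngn2(self) -> pd.Series | None:
        return self.frame["ngn2"] if "ngn2" in self.frame.columns else None

    def check_covers(self, counts: CountMatrix) -> None:
        missing = set(counts.sample_ids) - set(self.frame.index)
        if missing:
            raise ValueError(f"samples missing from table: {sorted(missing)[:5]}")

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        return SampleTable(self.frame.loc[list(sample_ids)].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe against which they are tested."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def restrict_to_universe(self) -> "GeneSetCollection":
        """Intersect each set with the universe (drops out-of-universe members)."""
        return GeneSetCollection(
            {name: members & self.universe for name, members in self.sets.items()},
            set(self.universe),
        )


@dataclass
class GeneAnnotation:
    """Gene id -> (species, length in bp)."""

    frame: pd.DataFrame  # index gene_id, columns species, length_bp

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.name != "gene_id":
            if "gene_id" in df.columns:
                df = df.set_index("gene_id")
            else:
                df = df.copy()
                df.index.name = "gene_id"
        if df.index.duplicated().any():
            raise ValueError("duplicate gene id in annotation")
        if "length_bp" not in df.columns:
            raise ValueError("annotation missing 'length_bp'")
        if (df["length_bp"] <= 0).any():
            bad = df.index[df["length_bp"] <= 0][0]
            raise ValueError(f"non-positive length for gene {bad!r}")
        self.frame = df

    def lengths(self, gene_ids: Iterable[str]) -> np.ndarray:
        gene_ids = list(gene_ids)
        missing = set(gene_ids) - set(self.frame.index)
        if missing:
            raise KeyError(f"no length for gene(s): {sorted(missing)[:5]}")
        return self.frame.loc[gene_ids, "length_bp"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(path: str | Path, species: str = "human",
                      alignment_ref: str = "single") -> CountMatrix:
    """Read a TSV count matrix (first column gene id, header = sample ids)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        n_fields = len(header)
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fields:
                raise ValueError(f"{path}:{lineno}: ragged row "
                                 f"({len(parts)} fields, expected {n_fields})")
            gene_ids.append(parts[0])
            row = []
            for v in parts[1:]:
                try:
                    x = float(v)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-numeric count {v!r}") from None
                if np.isnan(x):
                    raise ValueError(f"{path}:{lineno}: NaN count")
                if x < 0:
                    raise ValueError(f"{path}:{lineno}: negative count {v!r}")
                if x != int(x):
                    raise ValueError(f"{path}:{lineno}: non-integer count {v!r}")
                row.append(int(x))
            rows.append(row)
    counts = np.array(rows, dtype=np.int64).reshape(len(gene_ids), len(sample_ids))
    return CountMatrix(gene_ids, sample_ids, counts, species, alignment_ref)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_count_matrix_mtx(mtx_path: str | Path, species: str = "human",
                          alignment_ref: str = "single") -> CountMatrix:
    """Read a MatrixMarket triplet plus ``<stem>.genes.txt`` / ``<stem>.samples.txt`` sidecars.

    Coordinates in the .mtx file are 1-based per the MatrixMarket standard.
    """
    mtx_path = Path(mtx_path)
    stem = mtx_path.with_suffix("")
    gene_ids = Path(f"{stem}.genes.txt").read_text(encoding="utf-8").split()
    sample_ids = Path(f"{stem}.samples.txt").read_text(encoding="utf-8").split()
    mat = scipy.io.mmread(mtx_path)
    counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    return CountMatrix(gene_ids, sample_ids, counts, species, alignment_ref)


def write_count_matrix_mtx(cm: CountMatrix, mtx_path: str | Path) -> None:
    mtx_path = Path(mtx_path)
    stem = mtx_path.with_suffix("")
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(cm.counts))
    Path(f"{stem}.genes.txt").write_text("\n".join(cm.gene_ids) + "\n", encoding="utf-8")
    Path(f"{stem}.samples.txt").write_text("\n".join(cm.sample_ids) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# sample tables / annotations


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=True)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return GeneAnnotation(df)


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.frame.to_csv(path, sep="\t", index=True)


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``name<TAB>description<TAB>member...``.

    Duplicate members within a line are collapsed. Set order is preserved
    (Python dicts are ordered).
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(parts)} fields, need >=3")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(parts[2:])
    return GeneSetCollection(sets, set(universe) if universe is not None else set())


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na"] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# gene-level statistics


def read_gene_stats(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV (gene_id, z) of gene-level association statistics."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("gene stats table needs two columns (gene_id, z)")
    df = df.rename(columns={df.columns[0]: "gene_id", df.columns[1]: "z"})
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id in stats: {dup!r}")
    z = pd.to_numeric(df["z"], errors="coerce")
    if z.isna().any():
        bad = df.loc[z.isna(), "gene_id"].iloc[0]
        raise ValueError(f"non-numeric or missing Z for gene {bad!r}")
    df["z"] = z.astype(float)
    return df.set_index("gene_id")


def write_gene_stats(stats: Mapping[str, float] | pd.Series, path: str | Path) -> None:
    s = pd.Series(stats, name="z")
    s.index.name = "gene_id"
    s.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n", encoding="utf-8")
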