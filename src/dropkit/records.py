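"""Domain types and plain-text I/O.

The unit of input is a molecule record: one observed (cellular barcode, UMI,
gene) triple together with its read count and the per-position mean Phred
quality of the UMI bases.  Records are exchanged as a tab-separated table
(columns ``cb  umi  gene  reads  quals  [intergenic]``, header required,
qualities comma-separated) and the final output is a Matrix Market count
matrix with ``barcodes.tsv`` / ``features.tsv`` sidecars.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("dropkit")

_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class MoleculeRecord:
    """A single (cell barcode, UMI, gene) observation.

    ``quals`` holds the mean Phred score per UMI position (read-count
    weighted when duplicate rows are aggregated).  ``is_intergenic`` flags
    reads assigned outside annotated genes, carried through as a pseudo-gene
    label so downstream cell-quality features can be computed without a
    genome annotation.
    """

    cb: str
    umi: str
    gene: str
    reads: int
    quals: tuple[float, ...]
    is_intergenic: bool = False

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.umi):
            raise ValueError(
                f"quality vector length {len(self.quals)} != UMI length {len(self.umi)}"
            )
        if self.reads < 1:
            raise ValueError(f"read count must be >= 1, got {self.reads}")
        for seq, name in ((self.cb, "CB"), (self.umi, "UMI")):
            if not _ALPHABET.issuperset(seq):
                raise ValueError(f"{name} {seq!r} contains non-ACGT characters")


class Dataset:
    """A collection of molecule records with fixed UMI length.

    Internally a DataFrame (``cb``, ``umi``, ``gene``, ``reads``,
    ``intergenic``) plus a row-aligned ``(n, L)`` float array of per-position
    mean qualities.  Duplicate (cb, umi, gene) keys are aggregated on
    construction: reads are summed and qualities averaged with read-count
    weights, so total reads are conserved.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        quals: np.ndarray,
        umi_length: int,
        aggregate: bool = True,
    ) -> None:
        if len(df) != len(quals):
            raise ValueError("record table and quality array are misaligned")
        self.umi_length = int(umi_length)
        if aggregate and len(df):
            df, quals = _aggregate(df, quals)
        self.df = df.reset_index(drop=True)
        self.quals = np.asarray(quals, dtype=float).reshape(len(df), umi_length)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        cb: Sequence[str],
        umi: Sequence[str],
        gene: Sequence[str],
        reads: Sequence[int],
        quals: np.ndarray,
        intergenic: Sequence[bool] | None = None,
        umi_length: int | None = None,
    ) -> "Dataset":
        cb = list(cb)
        df = pd.DataFrame(
            {
                "cb": np.asarray(cb, dtype=object),
                "umi": np.asarray(umi, dtype=object),
                "gene": np.asarray(gene, dtype=object),
                "reads": np.asarray(reads, dtype=np.int64),
                "intergenic": (
                    np.zeros(len(cb), dtype=bool)
                    if intergenic is None
                    else np.asarray(intergenic, dtype=bool)
                ),
            }
        )
        if umi_length is None:
            if not len(df):
                raise ValueError("cannot infer UMI length from an empty dataset")
            umi_length = len(df["umi"].iloc[0])
        return cls(df, np.asarray(quals, dtype=float), umi_length)

    @classmethod
    def from_records(cls, records: Iterable[MoleculeRecord], umi_length: int | None = None) -> "Dataset":
        records = list(records)
        if not records and umi_length is None:
            raise ValueError("cannot infer UMI length from an empty dataset")
        if umi_length is None:
            umi_length = len(records[0].umi)
        quals = np.array([r.quals for r in records], dtype=float).reshape(len(records), umi_length)
        return cls.from_arrays(
            [r.cb for r in records],
            [r.umi for r in records],
            [r.gene for r in records],
            [r.reads for r in records],
            quals,
            [r.is_intergenic for r in records],
            umi_length,
        )

    # -- views -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_reads(self) -> int:
        return int(self.df["reads"].sum())

    def genic(self) -> "Dataset":
        """Records assigned to annotated genes (intergenic flag off)."""
        mask = ~self.df["intergenic"].to_numpy()
        return self.subset(np.flatnonzero(mask))

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            self.df.iloc[idx].reset_index(drop=True),
            self.quals[idx],
            self.umi_length,
            aggregate=False,
        )

    def cell_sizes(self) -> pd.Series:
        """Distinct molecules (records) per cellular barcode, genic only."""
        df = self.df
        return df.loc[~df["intergenic"], "cb"].value_counts()

    def cell_reads(self) -> pd.Series:
        return self.df.groupby("cb", sort=False)["reads"].sum()

    def records(self) -> list[MoleculeRecord]:
        return [
            MoleculeRecord(
                row.cb, row.umi, row.gene, int(row.reads), tuple(q), bool(row.intergenic)
            )
            for row, q in zip(self.df.itertuples(index=False), self.quals)
        ]


def _aggregate(df: pd.DataFrame, quals: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    codes, _ = pd.factorize(
        df["cb"].astype(str) + "\t" + df["umi"].astype(str) + "\t" + df["gene"].astype(str),
        sort=True,
    )
    n_groups = codes.max() + 1
    reads = np.asarray(df["reads"], dtype=np.int64)
    reads_sum = np.zeros(n_groups, dtype=np.int64)
    np.add.at(reads_sum, codes, reads)
    qsum = np.zeros((n_groups, quals.shape[1]))
    np.add.at(qsum, codes, quals * reads[:, None])
    inter = np.zeros(n_groups, dtype=bool)
    np.logical_or.at(inter, codes, np.asarray(df["intergenic"], dtype=bool))
    first = np.full(n_groups, -1, dtype=np.int64)
    seen_order = np.argsort(codes, kind="stable")
    first[codes[seen_order][::-1]] = seen_order[::-1]
    out = pd.DataFrame(
        {
            "cb": df["cb"].to_numpy()[first],
            "umi": df["umi"].to_numpy()[first],
            "gene": df["gene"].to_numpy()[first],
            "reads": reads_sum,
            "intergenic": inter,
        }
    )
    return out, qsum / reads_sum[:, None]


# ---------------------------------------------------------------------------
# record table I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("cb", "umi", "gene", "reads", "quals")


def read_records(path: str | Path, umi_length: int | None = None) -> Dataset:
    """Read a tab-separated molecule record table.

    Duplicate (cb, umi, gene) rows are aggregated (reads summed, qualities
    read-weighted).  The UMI length is validated against ``umi_length`` or
    inferred from the first row; ragged lengths, non-ACGT characters and
    non-positive read counts are hard errors naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"cb": str, "umi": str, "gene": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "intergenic" not in df.columns:
        df["intergenic"] = 0
    if not len(df):
        warnings.warn(f"{path}: empty record table")
        logger.warning("%s: empty record table", path)
        if umi_length is None:
            umi_length = 0
        return Dataset(
            pd.DataFrame(columns=["cb", "umi", "gene", "reads", "intergenic"]),
            np.empty((0, umi_length)),
            umi_length,
            aggregate=False,
        )
    if umi_length is None:
        umi_length = len(df["umi"].iloc[0])
    for i, (cb, umi, reads) in enumerate(zip(df["cb"], df["umi"], df["reads"])):
        if len(umi) != umi_length:
            raise ValueError(f"{path} row {i}: UMI {umi!r} has length != {umi_length}")
        if not _ALPHABET.issuperset(umi):
            raise ValueError(f"{path} row {i}: UMI {umi!r} contains non-ACGT characters")
        if not _ALPHABET.issuperset(cb):
            raise ValueError(f"{path} row {i}: CB {cb!r} contains non-ACGT characters")
        if reads < 1:
            raise ValueError(f"{path} row {i}: read count {reads} < 1")
    quals = np.array(
        [[float(x) for x in q.split(",")] for q in df["quals"]], dtype=float
    )
    if quals.shape[1] != umi_length:
        raise ValueError(f"{path}: quality vectors do not match UMI length {umi_length}")
    out = df[["cb", "umi", "gene", "reads"]].copy()
    out["intergenic"] = df["intergenic"].astype(bool)
    return Dataset(out, quals, umi_length)


def write_records(data: Dataset, path: str | Path) -> None:
    """Write a dataset back to the tab-separated record format."""
    out = data.df[["cb", "umi", "gene", "reads"]].copy()
    out["quals"] = [",".join(f"{q:g}" for q in row) for row in data.quals]
    out["intergenic"] = data.df["intergenic"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_whitelist(path: str | Path) -> list[str]:
    """Read a cellular-barcode whitelist, one sequence per line."""
    out = []
    with open(path) as fh:
        for line in fh:
            cb = line.strip()
            if not cb:
                continue
            if not _ALPHABET.issuperset(cb):
                raise ValueError(f"{path}: whitelist barcode {cb!r} contains non-ACGT characters")
            out.append(cb)
    return out


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene-by-cell molecular count matrix.

    Values are integers before collision adjustment and reals after.  Row
    order (genes) is lexicographic; column order (cells) is by descending
    molecule count then lexicographic, so output files are deterministic.
    """

    genes: list[str]
    cells: list[str]
    values: scipy.sparse.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell labels")
        self.values = scipy.sparse.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("matrix shape does not match labels")
        if len(self.values.data) and self.values.data.min() < 0:
            raise ValueError("negative counts")

    @classmethod
    def from_dataset(cls, data: Dataset) -> "CountMatrix":
        """Distinct-UMI counts per (gene, cell), intergenic records excluded."""
        df = data.df.loc[~data.df["intergenic"]]
        if not len(df):
            return cls([], [], scipy.sparse.csr_matrix((0, 0)))
        counts = df.groupby(["gene", "cb"], sort=False).size()
        genes = sorted(df["gene"].unique())
        cell_tot = df["cb"].value_counts()
        cells = sorted(cell_tot.index, key=lambda c: (-cell_tot[c], c))
        gi = {g: i for i, g in enumerate(genes)}
        ci = {c: i for i, c in enumerate(cells)}
        rows = [gi[g] for g, _ in counts.index]
        cols = [ci[c] for _, c in counts.index]
        mat = scipy.sparse.csr_matrix(
            (counts.to_numpy(dtype=float), (rows, cols)), shape=(len(genes), len(cells))
        )
        return cls(genes, cells, mat)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def write_count_matrix(matrix: CountMatrix, out_prefix: str | Path) -> None:
    """Write ``<prefix>matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``.

    Matrix Market coordinate format with 1-based indices; 17 significant
    digits so real-valued (collision-adjusted) matrices round-trip exactly.
    """
    prefix = str(out_prefix)
    parent = Path(prefix).parent if not prefix.endswith(("/", "\\")) else Path(prefix)
    parent.mkdir(parents=True, exist_ok=True)
    coo = matrix.values.tocoo()
    is_integral = len(coo.data) == 0 or np.all(coo.data == np.round(coo.data))
    data = coo.data.astype(np.int64) if is_integral else coo.data
    mat = scipy.sparse.coo_matrix((data, (coo.row, coo.col)), shape=coo.shape)
    scipy.io.mmwrite(prefix + "matrix.mtx", mat, precision=17)
    with open(prefix + "barcodes.tsv", "w") as fh:
        fh.writelines(c + "\n" for c in matrix.cells)
    with open(prefix + "features.tsv", "w") as fh:
        fh.writelines(g + "\n" for g in matrix.genes)


def read_count_matrix(prefix: str | Path) -> CountMatrix:
    prefix = str(prefix)
    mat = scipy.sparse.csr_matrix(scipy.io.mmread(prefix + "matrix.mtx"))
    with open(prefix + "barcodes.tsv") as fh:
        cells = [line.strip() for line in fh if line.strip()]
    with open(prefix + "features.tsv") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return CountMatrix(genes, cells, mat)
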