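"""Readers and writers for the tables and matrices the pipeline touches.

Formats are the plain-text ones emitted around droplet-based single-cell
V(D)J experiments: 10x-style contig annotation CSVs, MatrixMarket
gene-barcode count triplets with sidecar feature/barcode lists
(gzip-transparent), and tab-delimited cluster-label and specificity-catalog
tables. Every reader validates its schema and logs how many rows it drops;
every reader has a writer that round-trips losslessly.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

TCR_CHAINS = ("TRA", "TRB")

#: header names accepted for each logical contig column, in priority order.
#: Covers both 10x "filtered_contig_annotations.csv" and a minimal generic
#: header.
_CONTIG_COLUMN_ALIASES = {
    "barcode": ("barcode",),
    "chain": ("chain",),
    "v_gene": ("v_gene",),
    "j_gene": ("j_gene",),
    "cdr3": ("cdr3", "cdr3_aa"),
    "productive": ("productive",),
    "umis": ("umis", "reads"),
}


class FormatError(ValueError):
    """Raised when an input file does not match its declared schema."""


@dataclass(frozen=True)
class ContigRecord:
    """One V(D)J contig call for one barcode/chain."""

    barcode: str
    chain: str  # "TRA" or "TRB"
    v_gene: str
    j_gene: str
    cdr3_aa: str
    productive: bool
    umis: int


@dataclass
class CountMatrix:
    """A raw (unfiltered) gene x barcode UMI count matrix.

    ``counts`` is sparse CSC, genes on rows, barcodes on columns.
    ``mito_mask`` flags mitochondrial features by name prefix.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csc_matrix
    mito_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("count matrix contains negative entries")
        if self.mito_mask is None:
            self.mito_mask = np.zeros(len(self.genes), dtype=bool)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        if self.mito_mask.shape != (len(self.genes),):
            raise FormatError("mito_mask length must equal gene count")

    @property
    def library_sizes(self) -> np.ndarray:
        """Total UMIs per barcode."""
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(np.int64)

    def subset_barcodes(self, keep: list[str]) -> "CountMatrix":
        idx = {b: i for i, b in enumerate(self.barcodes)}
        cols = [idx[b] for b in keep]
        return CountMatrix(
            genes=list(self.genes),
            barcodes=list(keep),
            counts=self.counts[:, cols],
            mito_mask=self.mito_mask.copy(),
        )


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "t", "1", "yes"):
        return True
    if s in ("false", "f", "0", "no", "none"):
        return False
    raise FormatError(f"cannot interpret {value!r} as a boolean")


def read_contigs(path, productive_only: bool = True) -> list[ContigRecord]:
    """Read V(D)J contig annotations from a comma-delimited table.

    Only TRA/TRB loci are returned; contigs on other loci (TRG/TRD, IG)
    are dropped with a logged count.  With ``productive_only`` (the
    default), non-productive contigs and contigs with an empty CDR3 are
    dropped too, again with logged counts.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("contig file %s is empty", path)
        return []
    colmap = {}
    for logical, aliases in _CONTIG_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in df.columns:
                colmap[logical] = alias
                break
        else:
            raise FormatError(f"contig table {path} missing required column {logical!r}")

    chains = df[colmap["chain"]].str.upper()
    non_tcr = int((~chains.isin(TCR_CHAINS)).sum())
    if non_tcr:
        logger.info("dropped %d non-TRA/TRB contigs from %s", non_tcr, path)
    df = df[chains.isin(TCR_CHAINS)]

    records = []
    n_nonproductive = 0
    n_empty_cdr3 = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        productive = _parse_bool(row[colmap["productive"]])
        cdr3 = str(row[colmap["cdr3"]]).strip().upper()
        if productive_only:
            if not productive:
                n_nonproductive += 1
                continue
            if not cdr3 or cdr3 == "NONE":
                n_empty_cdr3 += 1
                continue
        records.append(
            ContigRecord(
                barcode=str(row[colmap["barcode"]]),
                chain=str(row[colmap["chain"]]).upper(),
                v_gene=str(row[colmap["v_gene"]]),
                j_gene=str(row[colmap["j_gene"]]),
                cdr3_aa=cdr3,
                productive=productive,
                umis=int(row[colmap["umis"]]),
            )
        )
    if n_nonproductive or n_empty_cdr3:
        logger.info(
            "dropped %d non-productive and %d empty-CDR3 contigs from %s",
            n_nonproductive, n_empty_cdr3, path,
        )
    if not records:
        logger.warning("no usable contigs read from %s", path)
    return records


def write_contigs(records: list[ContigRecord], path) -> None:
    """Write contig records as a minimal-header CSV readable by read_contigs."""
    df = pd.DataFrame(
        [
            {
                "barcode": r.barcode,
                "chain": r.chain,
                "v_gene": r.v_gene,
                "j_gene": r.j_gene,
                "cdr3": r.cdr3_aa,
                "productive": r.productive,
                "umis": r.umis,
            }
            for r in records
        ],
        columns=["barcode", "chain", "v_gene", "j_gene", "cdr3", "productive", "umis"],
    )
    df.to_csv(path, index=False)


def _read_id_lines(path) -> list[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        # 10x features.tsv carries extra columns; the first field is the id
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_count_matrix(matrix_path, features_path, barcodes_path,
                      mito_prefix: str = "MT-") -> CountMatrix:
    """Read a MatrixMarket integer triplet + feature/barcode line files."""
    counts = sp.csc_matrix(scipy.io.mmread(matrix_path))
    genes = _read_id_lines(features_path)
    barcodes = _read_id_lines(barcodes_path)
    if counts.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix header {counts.shape} does not match "
            f"{len(genes)} features / {len(barcodes)} barcodes"
        )
    mito_mask = np.array([g.startswith(mito_prefix) for g in genes])
    return CountMatrix(genes=genes, barcodes=barcodes, counts=counts,
                       mito_mask=mito_mask)


def write_count_matrix(matrix: CountMatrix, matrix_path, features_path,
                       barcodes_path) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(matrix.counts), field="integer")
    Path(features_path).write_text("".join(g + "\n" for g in matrix.genes))
    Path(barcodes_path).write_text("".join(b + "\n" for b in matrix.barcodes))


def read_cluster_labels(path) -> dict[str, str]:
    """Read a two-column (barcode, cluster) TSV into a mapping.

    Duplicate barcode rows are a format error: a cell belongs to exactly
    one cluster.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("barcode", "cluster"):
        if col not in df.columns:
            raise FormatError(f"cluster label table {path} missing column {col!r}")
    if df["barcode"].duplicated().any():
        dupes = df.loc[df["barcode"].duplicated(), "barcode"].unique()[:5]
        raise FormatError(f"duplicate barcode rows in {path}: {list(dupes)}")
    return dict(zip(df["barcode"], df["cluster"]))


def write_cluster_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame(
        {"barcode": list(labels.keys()), "cluster": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class SpecificityCatalog:
    """A curated CDR3beta -> pathology-association catalog (McPAS style)."""

    entries: list[tuple[str, str, str]]  # (cdr3b_aa, category, pathology)

    def sequences_by_category(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cdr3b, category, _ in self.entries:
            out.setdefault(category, set()).add(cdr3b)
        return out

    def __len__(self) -> int:
        return len(self.entries)


def read_catalog(path) -> SpecificityCatalog:
    """Read a three-column (cdr3b, category, pathology) TSV.

    Duplicate (sequence, category) pairs collapse to one entry; the first
    pathology annotation wins. CDR3 sequences are upper-cased so matching
    downstream is case-insensitive.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("catalog file %s is empty", path)
        return SpecificityCatalog(entries=[])
    for col in ("cdr3b", "category"):
        if col not in df.columns:
            raise FormatError(f"catalog {path} missing column {col!r}")
    pathology = df["pathology"] if "pathology" in df.columns else pd.Series([""] * len(df))
    seen = set()
    entries = []
    n_dup = 0
    for cdr3b, category, path_ann in zip(df["cdr3b"], df["category"], pathology):
        cdr3b = str(cdr3b).strip().upper()
        if not cdr3b:
            raise FormatError(f"catalog {path} contains an empty cdr3b sequence")
        key = (cdr3b, category)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        entries.append((cdr3b, category, path_ann))
    if n_dup:
        logger.info("collapsed %d duplicate (sequence, category) rows in %s", n_dup, path)
    return SpecificityCatalog(entries=entries)


def write_catalog(catalog: SpecificityCatalog, path) -> None:
    pd.DataFrame(catalog.entries, columns=["cdr3b", "category", "pathology"]).to_csv(
        path, sep="\t", index=False
    )
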