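"""Paired-chain clonotype assignment and clonal frequency tabulation.

A clonotype is the unique paired TRA-TRB identity of a T cell: the
6-tuple (TRAV, CDR3alpha, TRAJ, TRBV, CDR3beta, TRBJ). Only cells with
exactly one alpha chain and one beta chain are assigned a clonotype, so
that droplets with ambiguous chain content do not inflate clone counts.
Cluster-level repertoires treat each cluster as an independent sample.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import ContigRecord

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["trav", "cdr3a", "traj", "trbv", "cdr3b", "trbj"]

_ALLELE_RE = re.compile(r"\*\d+$")


class ClonotypeKey(NamedTuple):
    trav: str
    cdr3a: str
    traj: str
    trbv: str
    cdr3b: str
    trbj: str


@dataclass(frozen=True)
class Clonotype:
    key: ClonotypeKey
    count: int


@dataclass
class FrequencyVector:
    """Clone frequencies summing to one, all strictly positive."""

    f: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.size == 0:
            raise ValueError("frequency vector must be non-empty")
        if (self.f <= 0).any():
            raise ValueError("frequencies must be strictly positive")
        if abs(self.f.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {self.f.sum()}, not 1")

    @property
    def n(self) -> int:
        return int(self.f.size)


@dataclass
class ClonotypeAssignment:
    """Result of assigning clonotypes over a set of eligible barcodes."""

    assignments: dict[str, ClonotypeKey]
    unassigned: dict[str, str]  # barcode -> reason code
    table: pd.DataFrame  # KEY_COLUMNS + count, descending count


def strip_allele(gene: str) -> str:
    """Drop a trailing allele suffix ('TRBV9*01' -> 'TRBV9')."""
    return _ALLELE_RE.sub("", gene)


def assign_clonotypes(contigs: list[ContigRecord],
                      eligible_barcodes=None,
                      strip_alleles: bool = True) -> ClonotypeAssignment:
    """Assign paired-chain clonotypes to barcodes.

    A barcode receives a clonotype iff it carries exactly one unique TRA
    (V, CDR3, J) triple and exactly one unique TRB triple. All other
    eligible barcodes are recorded as unassigned with a reason code
    (no_tcr, no_alpha, no_beta, ambiguous_alpha, ambiguous_beta). CDR3
    sequences are compared upper-cased; allele suffixes on V/J names are
    stripped by default.
    """
    def norm_gene(g: str) -> str:
        return strip_allele(g) if strip_alleles else g

    per_bc: dict[str, dict[str, set]] = {}
    for c in contigs:
        if eligible_barcodes is not None and c.barcode not in eligible_barcodes:
            continue
        d = per_bc.setdefault(c.barcode, {"TRA": set(), "TRB": set()})
        d[c.chain].add((norm_gene(c.v_gene), c.cdr3_aa.upper(), norm_gene(c.j_gene)))

    universe = set(per_bc) if eligible_barcodes is None else set(eligible_barcodes)
    assignments: dict[str, ClonotypeKey] = {}
    unassigned: dict[str, str] = {}
    for bc in universe:
        ch = per_bc.get(bc)
        if ch is None or (not ch["TRA"] and not ch["TRB"]):
            unassigned[bc] = "no_tcr"
            continue
        n_a, n_b = len(ch["TRA"]), len(ch["TRB"])
        if n_b == 0:
            unassigned[bc] = "no_beta"
        elif n_a == 0:
            unassigned[bc] = "no_alpha"
        elif n_b > 1:
            unassigned[bc] = "ambiguous_beta"
        elif n_a > 1:
            unassigned[bc] = "ambiguous_alpha"
        else:
            (av, acdr3, aj), = ch["TRA"]
            (bv, bcdr3, bj), = ch["TRB"]
            assignments[bc] = ClonotypeKey(av, acdr3, aj, bv, bcdr3, bj)

    table = tabulate_clonotypes(assignments)
    logger.info("assigned clonotypes to %d/%d barcodes (%d unassigned)",
                len(assignments), len(universe), len(unassigned))
    return ClonotypeAssignment(assignments=assignments, unassigned=unassigned,
                               table=table)


def tabulate_clonotypes(assignments: dict[str, ClonotypeKey]) -> pd.DataFrame:
    """Aggregate barcode->key assignments into a clonotype count table."""
    if not assignments:
        return pd.DataFrame(columns=KEY_COLUMNS + ["count"])
    df = pd.DataFrame([k._asdict() for k in assignments.values()])
    table = (
        df.groupby(KEY_COLUMNS, sort=False).size().rename("count").reset_index()
    )
    return table.sort_values(
        ["count"] + KEY_COLUMNS, ascending=[False] + [True] * 6
    ).reset_index(drop=True)


def frequency_vector(table: pd.DataFrame) -> FrequencyVector:
    """Clone frequencies f_i = count_i / total, ordered by descending count
    then lexicographic key."""
    if table.empty:
        raise ValueError("cannot build a frequency vector from an empty clonotype table")
    ordered = table.sort_values(
        ["count"] + KEY_COLUMNS, ascending=[False] + [True] * 6
    )
    counts = ordered["count"].to_numpy(dtype=float)
    return FrequencyVector(counts / counts.sum())


def split_by_cluster(assignments: dict[str, ClonotypeKey],
                     labels: dict[str, str]) -> dict[str, pd.DataFrame]:
    """One clonotype table per cluster; unlabeled barcodes go to 'unlabeled'.

    The 'unlabeled' group is returned for auditability but callers doing
    per-cluster profiles should skip it.
    """
    by_cluster: dict[str, dict[str, ClonotypeKey]] = {}
    for bc, key in assignments.items():
        cluster = labels.get(bc, "unlabeled")
        by_cluster.setdefault(cluster, {})[bc] = key
    out = {}
    for cluster, asg in sorted(by_cluster.items()):
        table = tabulate_clonotypes(asg)
        if table.empty:
            logger.warning("cluster %s has no clonotyped cells; omitted", cluster)
            continue
        out[cluster] = table
    return out


def expansion_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Mark clones with >= 2 cells as expanded; return (table, expanded-cell
    fraction)."""
    out = table.copy()
    out["expanded"] = out["count"] >= 2
    total_cells = int(out["count"].sum())
    expanded_cells = int(out.loc[out["expanded"], "count"].sum())
    fraction = expanded_cells / total_cells if total_cells else 0.0
    return out, fraction
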