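"""CDR3beta specificity-composition analysis against a pathology catalog.

Observed clonotype CDR3beta sequences are matched exactly (case-normalized
amino-acid strings) against a curated catalog of pathology-associated TCR
sequences (McPAS-TCR style). A clone whose CDR3beta appears under several
catalog categories contributes to each of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import SpecificityCatalog


@dataclass
class SpecificityComposition:
    """Per-category clone/cell counts for one repertoire."""

    sample_id: str
    category_clone_counts: dict[str, int]
    category_cell_counts: dict[str, int]
    matched_clones: int
    matched_cells: int
    queried_clones: int

    def counts(self, unit: str = "clone") -> dict[str, int]:
        if unit == "clone":
            return dict(self.category_clone_counts)
        if unit == "cell":
            return dict(self.category_cell_counts)
        raise ValueError(f"unit must be 'clone' or 'cell', got {unit!r}")


def match_specificity(clonotypes: pd.DataFrame, catalog: SpecificityCatalog,
                      sample_id: str = "sample") -> SpecificityComposition:
    """Match clonotype CDR3beta sequences against the catalog.

    ``clonotypes`` is a clonotype table with at least ``cdr3b`` and
    ``count`` columns. Matching is exact on upper-cased amino-acid
    strings; multi-category sequences are counted once per category.
    """
    by_category = catalog.sequences_by_category()
    clone_counts = {cat: 0 for cat in by_category}
    cell_counts = {cat: 0 for cat in by_category}
    matched_clones = 0
    matched_cells = 0
    for cdr3b, cells in zip(clonotypes["cdr3b"], clonotypes["count"]):
        seq = str(cdr3b).upper()
        hit = False
        for cat, seqs in by_category.items():
            if seq in seqs:
                clone_counts[cat] += 1
                cell_counts[cat] += int(cells)
                hit = True
        if hit:
            matched_clones += 1
            matched_cells += int(cells)
    return SpecificityComposition(
        sample_id=sample_id,
        category_clone_counts=clone_counts,
        category_cell_counts=cell_counts,
        matched_clones=matched_clones,
        matched_cells=matched_cells,
        queried_clones=int(len(clonotypes)),
    )


def composition_table(compositions: list[SpecificityComposition],
                      unit: str = "clone") -> pd.DataFrame:
    """Side-by-side per-category table for two or more samples.

    Category rows are the union over samples, zero-filled; for each sample
    an absolute-count column and a within-sample fraction column
    (count / queried clones) are emitted, plus matched/queried totals.
    """
    categories = sorted({c for comp in compositions for c in comp.counts(unit)})
    data = {}
    for comp in compositions:
        counts = comp.counts(unit)
        col = [counts.get(cat, 0) for cat in categories]
        data[f"{comp.sample_id}_count"] = col
        denom = comp.queried_clones if unit == "clone" else max(
            sum(counts.values()) + 0, 1)
        if unit == "clone":
            data[f"{comp.sample_id}_fraction"] = [
                (c / denom if denom else 0.0) for c in col
            ]
        else:
            total_cells = comp.matched_cells if comp.matched_cells else 1
            data[f"{comp.sample_id}_fraction"] = [c / total_cells for c in col]
    table = pd.DataFrame(data, index=pd.Index(categories, name="category"))
    totals = {
        f"{comp.sample_id}_count": comp.matched_clones if unit == "clone"
        else comp.matched_cells
        for comp in compositions
    }
    table.attrs["matched_totals"] = totals
    return table
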