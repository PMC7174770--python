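"""Synthetic single-cell TCR + count-matrix experiments with ground truth.

Everything the pipeline consumes can be generated here: paired-chain
contig tables with a chosen clonal frequency distribution (uniform,
geometric, power-law) and injected chain-set doublets; raw gene-barcode
count matrices with an ambient-droplet background, negative-binomial real
cells, planted cluster markers and high-mitochondrial dying cells; and
mock specificity catalogs. Each generator is a pure function of its
parameters and seed, and every output passes the package's own readers.

Synthetic V/J gene names carry the reserved SYN prefix (SYNTRAV1, ...) so
fixtures can never be mistaken for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ContigRecord, CountMatrix, SpecificityCatalog

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class RepertoireSpec:
    """Parameters of one synthetic repertoire."""

    n_clones: int
    n_cells: int
    distribution: str = "uniform"  # uniform | geometric | powerlaw
    ratio: float = 0.95            # geometric decay r, clone i freq ~ r^i
    exponent: float = 2.0          # power-law exponent, freq ~ i^-exponent
    doublet_rate: float = 0.0
    catalog_spike: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.distribution == "geometric" and not (0 < self.ratio < 1):
            raise ValueError("geometric ratio must be in (0, 1)")
        if self.distribution == "powerlaw" and self.exponent <= 1:
            raise ValueError("power-law exponent must be > 1")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must be in [0, 1)")
        if len(self.catalog_spike) > self.n_clones:
            raise ValueError("more catalog spikes than clones")


@dataclass
class ExperimentTruth:
    """Ground truth accompanying generated data."""

    clone_frequencies: np.ndarray | None = None
    barcode_clone: dict[str, int] | None = None       # primary clone index
    doublet_flags: dict[str, bool] = field(default_factory=dict)
    detectable_doublet: dict[str, bool] = field(default_factory=dict)
    real_cell_flags: dict[str, bool] = field(default_factory=dict)
    dying_cells: list[str] = field(default_factory=list)
    marker_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    cluster_labels: dict[str, str] = field(default_factory=dict)


def clone_frequencies(spec: RepertoireSpec) -> np.ndarray:
    """Normalized clone frequencies for the spec's distribution."""
    i = np.arange(1, spec.n_clones + 1, dtype=float)
    if spec.distribution == "uniform":
        w = np.ones_like(i)
    elif spec.distribution == "geometric":
        w = spec.ratio ** i
    elif spec.distribution == "powerlaw":
        w = i ** (-spec.exponent)
    else:
        raise ValueError(f"unknown distribution {spec.distribution!r}")
    return w / w.sum()


def _random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(10, 19))
    middle = "".join(rng.choice(_AMINO_ACIDS, size=length - 2))
    return "C" + middle + "F"


def _clone_chain_pool(spec: RepertoireSpec, rng: np.random.Generator):
    """Distinct TRA and TRB (V, CDR3, J) triples per clone."""
    cdr3a, cdr3b = set(), set()
    clones = []
    spikes = [s.upper() for s in spec.catalog_spike]
    for i in range(spec.n_clones):
        while True:
            a = _random_cdr3(rng)
            if a not in cdr3a:
                cdr3a.add(a)
                break
        if i < len(spikes):
            b = spikes[i]
        else:
            while True:
                b = _random_cdr3(rng)
                if b not in cdr3b and b not in spikes:
                    break
        cdr3b.add(b)
        clones.append(
            {
                "tra": (f"SYNTRAV{i + 1}", a, f"SYNTRAJ{i + 1}"),
                "trb": (f"SYNTRBV{i + 1}", b, f"SYNTRBJ{i + 1}"),
            }
        )
    return clones


def simulate_repertoire(spec: RepertoireSpec):
    """Generate a paired-chain contig table with known clonal structure.

    Each cell draws a clone from the spec's frequency distribution and
    carries that clone's TRA and TRB contigs. Doublets are made by adding
    the chain set of a second, independently drawn clone to a fraction
    ``doublet_rate`` of cells; a doublet is detectable by chain counting
    only when the partner clone differs. Returns (contigs, truth).
    """
    rng = np.random.default_rng(spec.seed)
    freqs = clone_frequencies(spec)
    pool = _clone_chain_pool(spec, rng)
    clone_of_cell = rng.choice(spec.n_clones, size=spec.n_cells, p=freqs)
    is_doublet = rng.random(spec.n_cells) < spec.doublet_rate
    partner = rng.choice(spec.n_clones, size=spec.n_cells, p=freqs)

    contigs: list[ContigRecord] = []
    truth = ExperimentTruth(clone_frequencies=freqs, barcode_clone={})
    for j in range(spec.n_cells):
        bc = f"SYNCELL{j:06d}-1"
        clone_ids = [int(clone_of_cell[j])]
        if is_doublet[j]:
            clone_ids.append(int(partner[j]))
        for ci in clone_ids:
            for chain, triple in (("TRA", pool[ci]["tra"]), ("TRB", pool[ci]["trb"])):
                v, cdr3, jg = triple
                contigs.append(
                    ContigRecord(barcode=bc, chain=chain, v_gene=v, j_gene=jg,
                                 cdr3_aa=cdr3, productive=True,
                                 umis=int(rng.integers(1, 30)))
                )
        truth.barcode_clone[bc] = int(clone_of_cell[j])
        truth.doublet_flags[bc] = bool(is_doublet[j])
        truth.detectable_doublet[bc] = bool(
            is_doublet[j] and partner[j] != clone_of_cell[j]
        )
        truth.real_cell_flags[bc] = True
    return contigs, truth


def _ambient_profile(n_genes: int, shape: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Power-law gene composition of the ambient soup, in shuffled order."""
    p = (np.arange(1, n_genes + 1, dtype=float)) ** (-shape)
    rng.shuffle(p)
    return p / p.sum()


def simulate_counts(n_real_cells: int = 500, n_ambient_barcodes: int = 5000,
                    n_genes: int = 200, ambient_profile_shape: float = 1.0,
                    marker_spec: dict[str, dict[str, float]] | None = None,
                    clusters: tuple[str, ...] = ("C1", "C2", "C3", "C4"),
                    mean_library_size: int = 2000, dispersion: float = 0.5,
                    n_mito_genes: int = 10, mito_background_frac: float = 0.05,
                    n_dying: int = 0, dying_mito_frac: float = 0.6,
                    ambient_max_total: int = 100, seed: int = 0,
                    real_barcodes: list[str] | None = None):
    """Generate a raw gene-barcode matrix with ambient background.

    Real cells are negative binomial per gene (variance mu + d*mu^2,
    ``dispersion`` = d) around gene means scaled to ``mean_library_size``,
    split evenly over ``clusters``; ``marker_spec`` maps cluster -> gene ->
    fold-change for planted markers. Ambient barcodes are multinomial
    draws from a fixed power-law ambient profile with totals at most
    ``ambient_max_total``. The first ``n_mito_genes`` features are named
    with the MT- prefix and hold ``mito_background_frac`` of the mean
    library; ``n_dying`` designated cells get their mitochondrial load
    inflated to ``dying_mito_frac``.

    Returns (CountMatrix, cluster labels for real cells, ExperimentTruth).
    """
    rng = np.random.default_rng(seed)
    mito_genes = [f"MT-SYN{i + 1}" for i in range(n_mito_genes)]
    body_genes = [f"SYNG{i + 1:04d}" for i in range(n_genes - n_mito_genes)]
    genes = mito_genes + body_genes

    # gene means: gamma-distributed, rescaled so mito block carries the
    # background fraction and totals hit mean_library_size
    mu = rng.gamma(shape=2.0, scale=1.0, size=n_genes)
    mito_idx = np.arange(n_mito_genes)
    body_idx = np.arange(n_mito_genes, n_genes)
    mu[mito_idx] *= mito_background_frac * mean_library_size / mu[mito_idx].sum()
    mu[body_idx] *= (1 - mito_background_frac) * mean_library_size / mu[body_idx].sum()

    if real_barcodes is None:
        real_barcodes = [f"SYNCELL{j:06d}-1" for j in range(n_real_cells)]
    elif len(real_barcodes) != n_real_cells:
        raise ValueError("real_barcodes length must equal n_real_cells")
    cluster_of = np.array([clusters[j % len(clusters)] for j in range(n_real_cells)])
    perm = rng.permutation(n_real_cells)
    cluster_of = cluster_of[perm]

    gene_index = {g: i for i, g in enumerate(genes)}
    marker_spec = marker_spec or {}
    mu_cells = np.tile(mu[:, None], (1, n_real_cells))
    for cl, gene_fc in marker_spec.items():
        cols = np.flatnonzero(cluster_of == cl)
        for g, fc in gene_fc.items():
            mu_cells[gene_index[g], cols] *= fc

    dying = list(np.array(real_barcodes)[
        rng.choice(n_real_cells, size=n_dying, replace=False)
    ]) if n_dying else []
    dying_set = set(dying)
    for j, bc in enumerate(real_barcodes):
        if bc in dying_set:
            mito_total = mu_cells[mito_idx, j].sum()
            body_total = mu_cells[body_idx, j].sum()
            # scale mito means so the expected mito fraction hits the target
            factor = dying_mito_frac * body_total / (mito_total * (1 - dying_mito_frac))
            mu_cells[mito_idx, j] *= factor

    n_nb = 1.0 / dispersion
    p_nb = n_nb / (n_nb + mu_cells)
    real_counts = rng.negative_binomial(n_nb, p_nb)

    ambient_p = _ambient_profile(n_genes, ambient_profile_shape, rng)
    ambient_totals = rng.integers(1, ambient_max_total + 1, size=n_ambient_barcodes)
    ambient_counts = np.stack(
        [rng.multinomial(int(t), ambient_p) for t in ambient_totals], axis=1
    ) if n_ambient_barcodes else np.zeros((n_genes, 0), dtype=np.int64)

    ambient_barcodes = [f"SYNAMB{j:06d}-1" for j in range(n_ambient_barcodes)]
    barcodes = list(real_barcodes) + ambient_barcodes
    counts = sp.csc_matrix(
        np.concatenate([real_counts, ambient_counts], axis=1)
    )
    matrix = CountMatrix(
        genes=genes, barcodes=barcodes, counts=counts,
        mito_mask=np.array([g.startswith("MT-") for g in genes]),
    )
    labels = dict(zip(real_barcodes, cluster_of))
    truth = ExperimentTruth(
        real_cell_flags={**{b: True for b in real_barcodes},
                         **{b: False for b in ambient_barcodes}},
        dying_cells=dying,
        marker_genes=marker_spec,
        cluster_labels=labels,
    )
    return matrix, labels, truth


def simulate_experiment(n_real_cells: int = 500, n_ambient_barcodes: int = 5000,
                        doublet_rate: float = 0.02, n_clones: int = 50,
                        distribution: str = "geometric", seed: int = 0,
                        **counts_kwargs):
    """A full experiment: count matrix + matching contig table + truth.

    Real-cell barcodes are shared between the count matrix and the contig
    table; doublet droplets carry merged chain sets (the transcriptome
    side of doublets is not modelled — chain counting is the intended
    detector here).
    """
    rep_spec = RepertoireSpec(
        n_clones=n_clones, n_cells=n_real_cells, distribution=distribution,
        doublet_rate=doublet_rate, seed=seed,
    )
    contigs, rep_truth = simulate_repertoire(rep_spec)
    real_barcodes = [f"SYNCELL{j:06d}-1" for j in range(n_real_cells)]
    matrix, labels, counts_truth = simulate_counts(
        n_real_cells=n_real_cells, n_ambient_barcodes=n_ambient_barcodes,
        seed=seed + 1, real_barcodes=real_barcodes, **counts_kwargs,
    )
    truth = ExperimentTruth(
        clone_frequencies=rep_truth.clone_frequencies,
        barcode_clone=rep_truth.barcode_clone,
        doublet_flags=rep_truth.doublet_flags,
        detectable_doublet=rep_truth.detectable_doublet,
        real_cell_flags=counts_truth.real_cell_flags,
        dying_cells=counts_truth.dying_cells,
        marker_genes=counts_truth.marker_genes,
        cluster_labels=counts_truth.cluster_labels,
    )
    return matrix, contigs, labels, truth


def simulate_ambient_null(n_ambient_barcodes: int = 2000,
                          n_null_barcodes: int = 500, n_genes: int = 200,
                          ambient_profile_shape: float = 1.0,
                          null_total_range: tuple[int, int] = (150, 400),
                          ambient_max_total: int = 100,
                          seed: int = 0) -> CountMatrix:
    """Matrix where every above-ambient barcode IS an ambient multinomial.

    All ``n_null_barcodes`` high-count barcodes are drawn from the same
    multinomial as the ambient soup, so an ambient-deviation test should
    retain at most its FDR's worth of them. Used for calibration checks.
    """
    rng = np.random.default_rng(seed)
    p = _ambient_profile(n_genes, ambient_profile_shape, rng)
    amb_totals = rng.integers(1, ambient_max_total + 1, size=n_ambient_barcodes)
    null_totals = rng.integers(null_total_range[0], null_total_range[1] + 1,
                               size=n_null_barcodes)
    cols = [rng.multinomial(int(t), p) for t in null_totals]
    cols += [rng.multinomial(int(t), p) for t in amb_totals]
    barcodes = [f"SYNNULL{j:06d}-1" for j in range(n_null_barcodes)] + \
               [f"SYNAMB{j:06d}-1" for j in range(n_ambient_barcodes)]
    genes = [f"SYNG{i + 1:04d}" for i in range(n_genes)]
    counts = sp.csc_matrix(np.stack(cols, axis=1))
    return CountMatrix(genes=genes, barcodes=barcodes, counts=counts)


def simulate_catalog(n_entries: int = 30,
                     categories: tuple[str, ...] = ("Autoimmune", "Pathogens",
                                                    "Cancer", "Allergy"),
                     seed: int = 0) -> SpecificityCatalog:
    """Mock pathology-association catalog with CDR3beta-like sequences."""
    if n_entries < len(categories):
        raise ValueError("need at least one entry per category")
    rng = np.random.default_rng(seed)
    entries = []
    seen = set()
    for i in range(n_entries):
        while True:
            seq = _random_cdr3(rng)
            if seq not in seen:
                seen.add(seq)
                break
        cat = categories[i % len(categories)]
        entries.append((seq, cat, f"SYNPATH{i + 1}"))
    return SpecificityCatalog(entries=entries)
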