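"""Droplet barcode quality control for single-cell RNA + V(D)J data.

Four filters, applied in order, decide which droplet barcodes are treated
as cells:

1. an ambient-RNA goodness-of-fit test: barcodes are compared against the
   expression profile estimated from low-count droplets (<= ``ambient_max``
   total UMIs) and retained when they deviate from it at a Benjamini-
   Hochberg FDR below ``fdr``;
2. a knee-point filter on the barcode-rank curve: the threshold is the
   steepest drop of the smoothed log-log UMI rank curve;
3. robust outlier removal on per-cell covariates (library size, genes
   detected: both sides; mitochondrial fraction: upper side only) at
   ``n_mads`` median absolute deviations from the median;
4. a TCR chain-count doublet filter: droplets carrying more than one
   unique TRB chain or more than two unique TRA chains are presumed
   doublets.

The ambient test here is a deliberately simple Monte-Carlo multinomial
goodness-of-fit (one pseudocount per gene in the ambient profile, no
overdispersion model); see the methods note for what that simplification
does and does not capture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import ContigRecord, CountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellQCMetrics:
    """Per-barcode QC covariates."""

    barcode: str
    library_size: int
    n_genes: int
    mito_fraction: float


def compute_qc_metrics(matrix: CountMatrix) -> pd.DataFrame:
    """Per-barcode library size, genes detected and mitochondrial fraction."""
    counts = sp.csc_matrix(matrix.counts)
    lib = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = np.asarray(counts[matrix.mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(lib > 0, mito / np.maximum(lib, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "library_size": lib.astype(np.int64),
            "n_genes": n_genes.astype(np.int64),
            "mito_fraction": mito_frac,
        }
    ).set_index("barcode")


# ---------------------------------------------------------------------------
# stage 1: ambient-profile deviation test


@dataclass
class AmbientTestResult:
    retained: set
    pvalues: pd.Series     # per tested (non-ambient) barcode
    qvalues: pd.Series
    ambient_profile: np.ndarray
    n_ambient: int


def _multinomial_loglik(x: np.ndarray, log_p: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood, including the coefficient term.

    x may be (n_genes,) or (n_draws, n_genes).
    """
    x = np.atleast_2d(x)
    total = x.sum(axis=1)
    return gammaln(total + 1) - gammaln(x + 1).sum(axis=1) + x @ log_p


def ambient_test(matrix: CountMatrix, ambient_max: int = 100,
                 fdr: float = 0.01, n_iters: int = 1000,
                 seed: int = 0) -> AmbientTestResult:
    """Test each above-ambient barcode against the ambient RNA profile.

    The ambient profile is the gene-wise sum of counts over barcodes with
    at most ``ambient_max`` total UMIs, plus one pseudocount per gene,
    normalized. For each barcode above ``ambient_max`` the p-value is the
    Monte-Carlo tail probability that a multinomial draw from the ambient
    profile with the same total has log-likelihood at or below the
    observed one, with the (r+1)/(n_iters+1) estimator; retention is at
    Benjamini-Hochberg q < ``fdr``. Ambient-set barcodes are never
    retained.
    """
    if n_iters < 100:
        raise ValueError("n_iters must be at least 100")
    lib = matrix.library_sizes
    ambient_cols = np.flatnonzero(lib <= ambient_max)
    if ambient_cols.size == 0:
        raise ValueError(
            f"no barcodes with <= {ambient_max} total UMIs to estimate the "
            "ambient profile; raise ambient_max"
        )
    counts = sp.csc_matrix(matrix.counts)
    ambient_sum = np.asarray(counts[:, ambient_cols].sum(axis=1)).ravel()
    profile = (ambient_sum + 1.0) / (ambient_sum + 1.0).sum()
    log_p = np.log(profile)

    test_cols = np.flatnonzero(lib > ambient_max)
    rng = np.random.default_rng(seed)
    pvals = np.ones(test_cols.size)
    dense = counts[:, test_cols].toarray().T  # (n_test, n_genes)
    obs_ll = _multinomial_loglik(dense, log_p)
    # share simulated null log-likelihoods across barcodes with equal totals
    totals = dense.sum(axis=1).astype(np.int64)
    for total in np.unique(totals):
        draws = rng.multinomial(int(total), profile, size=n_iters)
        null_ll = _multinomial_loglik(draws, log_p)
        sel = totals == total
        r = (null_ll[None, :] <= obs_ll[sel, None]).sum(axis=1)
        pvals[sel] = (r + 1.0) / (n_iters + 1.0)

    barcodes = np.asarray(matrix.barcodes, dtype=object)
    p_series = pd.Series(pvals, index=barcodes[test_cols])
    if test_cols.size:
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        qvals = np.array([])
    q_series = pd.Series(qvals, index=barcodes[test_cols])
    retained = set(q_series.index[q_series < fdr])
    logger.info(
        "ambient test: %d ambient barcodes, %d tested, %d retained at FDR %g",
        ambient_cols.size, test_cols.size, len(retained), fdr,
    )
    return AmbientTestResult(
        retained=retained,
        pvalues=p_series,
        qvalues=q_series,
        ambient_profile=profile,
        n_ambient=int(ambient_cols.size),
    )


# ---------------------------------------------------------------------------
# stage 2: knee point on the barcode-rank curve


def knee_threshold(library_sizes, window: int = 5,
                   slope_floor: float = 1e-3) -> int:
    """UMI threshold at the steepest drop of the log-log barcode-rank curve.

    Library sizes are sorted descending; on the (log10 rank, log10 size)
    curve, log-size is smoothed with a centred moving average of
    ``window`` points and the threshold is the size at the rank minimizing
    the discrete first derivative. If the derivative never falls below
    ``-slope_floor`` the curve is effectively flat: a warning is logged and
    the minimum size is returned (a no-op filter).

    Barcodes with ``library_size >= threshold`` pass.
    """
    sizes = np.sort(np.asarray(library_sizes, dtype=float))[::-1]
    if np.unique(sizes).size < 10:
        raise ValueError("knee detection requires at least 10 distinct library sizes")
    pos = sizes[sizes > 0]
    # collapse tied sizes to one point at their average rank: plateaus of
    # duplicated small sizes would otherwise dominate the derivative through
    # vanishing log-rank spacing
    uniq, counts = np.unique(pos, return_counts=True)
    uniq, counts = uniq[::-1], counts[::-1]  # descending unique sizes
    avg_rank = np.cumsum(counts) - (counts - 1) / 2.0
    x = np.log10(avg_rank)
    y = np.log10(uniq)
    kernel = np.ones(window) / window
    y_smooth = np.convolve(np.pad(y, window // 2, mode="edge"), kernel, mode="valid")
    y_smooth = y_smooth[: y.size]
    deriv = np.diff(y_smooth) / np.diff(x)
    if deriv.min() >= -slope_floor:
        logger.warning("barcode-rank curve has no drop steeper than %g; "
                       "knee filter is a no-op", slope_floor)
        return int(pos.min())
    # locate the drop region on the smoothed curve, then refine to the
    # steepest raw segment nearby (smoothing blurs the cliff edge)
    knee = int(np.argmin(deriv))
    raw_deriv = np.diff(y) / np.diff(x)
    lo, hi = max(0, knee - window), min(deriv.size, knee + window + 1)
    knee = lo + int(np.argmin(raw_deriv[lo:hi]))
    # threshold at the upper end of the steepest segment: the last size
    # before the drop passes, everything past the drop fails
    return int(uniq[knee])


# ---------------------------------------------------------------------------
# stage 3: MAD outlier masks

_MAD_CONSISTENCY = 1.4826  # normal-consistency constant


def mad_outlier_mask(values, n_mads: float = 3.0, sides: str = "both") -> np.ndarray:
    """Boolean keep-mask for values within ``n_mads`` MADs of the median.

    MAD is scaled by 1.4826 for normal consistency. ``sides="both"`` keeps
    |x - median| <= n_mads * MAD; ``sides="upper"`` keeps
    x <= median + n_mads * MAD (low values always pass). A zero MAD keeps
    everything and logs a degeneracy warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad_outlier_mask requires non-empty input")
    if n_mads <= 0:
        raise ValueError("n_mads must be positive")
    if sides not in ("both", "upper"):
        raise ValueError(f"sides must be 'both' or 'upper', got {sides!r}")
    med = np.median(values)
    mad = _MAD_CONSISTENCY * np.median(np.abs(values - med))
    if mad == 0:
        logger.warning("MAD is zero (degenerate spread); keeping all values")
        return np.ones(values.size, dtype=bool)
    if sides == "both":
        return np.abs(values - med) <= n_mads * mad
    return values <= med + n_mads * mad


# ---------------------------------------------------------------------------
# stage 4: TCR chain-count doublet filter


def chain_doublet_filter(contigs: list[ContigRecord],
                         barcodes=None) -> set:
    """Keep barcodes whose unique chain counts are compatible with one cell.

    Unique chains are counted on the (V gene, CDR3, J gene) triple. A
    barcode is excluded iff it has more than one unique TRB chain OR more
    than two unique TRA chains. Barcodes with no contigs pass this filter;
    pass ``barcodes`` to include contig-less barcodes in the returned set.
    """
    chains: dict[str, dict[str, set]] = {}
    for c in contigs:
        per_bc = chains.setdefault(c.barcode, {"TRA": set(), "TRB": set()})
        per_bc[c.chain].add((c.v_gene, c.cdr3_aa, c.j_gene))
    universe = set(barcodes) if barcodes is not None else set(chains)
    excluded = {
        bc for bc, ch in chains.items()
        if len(ch["TRB"]) > 1 or len(ch["TRA"]) > 2
    }
    return universe - excluded


# ---------------------------------------------------------------------------
# the cascade


@dataclass
class QCConfig:
    """Knobs for the four-stage cascade. Defaults follow the pipeline's

    published operating point: ambient set at <=100 UMIs, FDR 0.01,
    3-MAD outlier bounds."""

    ambient_enabled: bool = True
    ambient_max: int = 100
    fdr: float = 0.01
    ambient_iters: int = 1000
    knee_enabled: bool = True
    knee_window: int = 5
    knee_slope_floor: float = 1e-3
    mad_enabled: bool = True
    n_mads: float = 3.0
    mad_log_scale: bool = False
    doublet_enabled: bool = True
    seed: int = 0


@dataclass
class QCReport:
    """Per-stage accounting for one cascade run."""

    stages: pd.DataFrame  # columns: stage, kept, removed, threshold
    kept_barcodes: list[str]
    seed: int
    config: QCConfig = field(repr=False, default=None)


def run_qc_cascade(matrix: CountMatrix, contigs: list[ContigRecord],
                   config: QCConfig | None = None) -> QCReport:
    """Run ambient test -> knee -> MAD triple -> chain doublets, in order.

    Each stage operates on the survivors of the previous one; MAD medians
    are recomputed on the current survivor set.
    """
    config = config or QCConfig()
    kept = list(matrix.barcodes)
    rows = [{"stage": "input", "kept": len(kept), "removed": 0, "threshold": ""}]

    if config.ambient_enabled:
        res = ambient_test(matrix, ambient_max=config.ambient_max,
                           fdr=config.fdr, n_iters=config.ambient_iters,
                           seed=config.seed)
        new = [b for b in kept if b in res.retained]
        rows.append({"stage": "ambient_test", "kept": len(new),
                     "removed": len(kept) - len(new),
                     "threshold": f"q<{config.fdr}"})
        kept = new

    if config.knee_enabled:
        sub = matrix.subset_barcodes(kept)
        lib = dict(zip(sub.barcodes, sub.library_sizes))
        thr = knee_threshold(list(lib.values()), window=config.knee_window,
                             slope_floor=config.knee_slope_floor)
        new = [b for b in kept if lib[b] >= thr]
        rows.append({"stage": "knee", "kept": len(new),
                     "removed": len(kept) - len(new), "threshold": str(thr)})
        kept = new

    if config.mad_enabled:
        metrics = compute_qc_metrics(matrix.subset_barcodes(kept))
        lib = metrics["library_size"].to_numpy(dtype=float)
        ngenes = metrics["n_genes"].to_numpy(dtype=float)
        if config.mad_log_scale:
            lib = np.log1p(lib)
            ngenes = np.log1p(ngenes)
        keep_mask = (
            mad_outlier_mask(lib, config.n_mads, "both")
            & mad_outlier_mask(ngenes, config.n_mads, "both")
            & mad_outlier_mask(metrics["mito_fraction"].to_numpy(),
                               config.n_mads, "upper")
        )
        new = [b for b, k in zip(kept, keep_mask) if k]
        rows.append({"stage": "mad_outliers", "kept": len(new),
                     "removed": len(kept) - len(new),
                     "threshold": f"{config.n_mads} MADs"})
        kept = new

    if config.doublet_enabled:
        passed = chain_doublet_filter(contigs, barcodes=kept)
        new = [b for b in kept if b in passed]
        rows.append({"stage": "chain_doublets", "kept": len(new),
                     "removed": len(kept) - len(new),
                     "threshold": ">1 TRB or >2 TRA"})
        kept = new

    return QCReport(stages=pd.DataFrame(rows), kept_barcodes=kept,
                    seed=config.seed, config=config)
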