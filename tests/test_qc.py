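import numpy as np
import pytest
import scipy.sparse as sp

from repdiv.io import CountMatrix
from repdiv.qc import (
    QCConfig,
    ambient_test,
    chain_doublet_filter,
    compute_qc_metrics,
    knee_threshold,
    mad_outlier_mask,
    run_qc_cascade,
)
from repdiv.simulate import simulate_ambient_null, simulate_experiment

from conftest import make_contig


class TestMadOutlierMask:
    def test_hand_computed_bounds(self):
        # median 10.5, MAD = 1.4826 * 1.5 = 2.2239, 3-MAD band (3.83, 17.17)
        keep = mad_outlier_mask([8, 9, 10, 11, 12, 100], n_mads=3, sides="both")
        assert list(keep) == [True, True, True, True, True, False]

    def test_constant_vector_keeps_all(self):
        assert mad_outlier_mask([5, 5, 5, 5], 3, "both").all()

    def test_upper_side_keeps_low_extreme(self):
        keep = mad_outlier_mask([-100, 9, 10, 11, 12], 3, "upper")
        assert keep[0]

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (0.5, 10.0), (3.0, -7.0)])
    def test_affine_equivariance_both_sides(self, rng, a, b):
        x = rng.normal(size=200)
        x[:5] += 10  # inject outliers
        keep = mad_outlier_mask(x, 3, "both")
        assert (mad_outlier_mask(a * x + b, 3, "both") == keep).all()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            mad_outlier_mask([], 3)


class TestKneeThreshold:
    @staticmethod
    def _brute_force_knee(sizes):
        """Independent scan: steepest drop over all unique-size segments of
        the (unsmoothed) log rank / log size curve."""
        s = np.sort(np.asarray(sizes, float))[::-1]
        s = s[s > 0]
        uniq = sorted(set(s), reverse=True)
        ranks = []
        start = 1
        for u in uniq:
            n = int((s == u).sum())
            ranks.append(start + (n - 1) / 2.0)
            start += n
        best, best_slope = 0, np.inf
        for i in range(len(uniq) - 1):
            slope = (np.log10(uniq[i + 1]) - np.log10(uniq[i])) / (
                np.log10(ranks[i + 1]) - np.log10(ranks[i]))
            if slope < best_slope:
                best, best_slope = i, slope
        return uniq[best]

    def test_two_plateau_curve_splits_plateaus(self, rng):
        high = rng.integers(9500, 10500, size=100)
        low = rng.integers(8, 12, size=10000)
        sizes = np.concatenate([high, low])
        thr = knee_threshold(sizes)
        assert 12 < thr <= 10500
        assert (high >= thr).all()
        assert (low < thr).all()
        # independent brute-force scan agrees the drop sits between plateaus
        oracle = self._brute_force_knee(sizes)
        assert 12 < oracle <= 10500
        assert (high >= oracle).all()

    def test_flat_curve_noop_fallback(self):
        # strictly uniform sizes trip the <10-distinct precondition
        with pytest.raises(ValueError):
            knee_threshold([50] * 100)
        # a flat-but-distinct curve falls back to the minimum size
        flat = np.linspace(1000, 1000.5, 50)
        assert knee_threshold(flat) == int(flat.min())

    def test_scale_invariance_of_passing_set(self, rng):
        high = rng.integers(4000, 6000, size=50)
        low = rng.integers(5, 30, size=2000)
        sizes = np.concatenate([high, low])
        thr1 = knee_threshold(sizes)
        thr2 = knee_threshold(2 * sizes)
        assert ((sizes >= thr1) == (2 * sizes >= thr2)).all()

    def test_too_few_distinct_sizes(self):
        with pytest.raises(ValueError):
            knee_threshold([1, 2, 3, 4, 5] * 10)


def _matrix_from_dense(dense, mito_rows=()):
    n_genes, n_bc = dense.shape
    mask = np.zeros(n_genes, bool)
    mask[list(mito_rows)] = True
    return CountMatrix(genes=[f"G{i}" for i in range(n_genes)],
                       barcodes=[f"B{j}" for j in range(n_bc)],
                       counts=sp.csc_matrix(dense), mito_mask=mask)


class TestAmbientTest:
    def test_null_retention_at_most_fdr(self):
        """Ambient-like high-count barcodes are retained at <= FDR rate."""
        matrix = simulate_ambient_null(n_ambient_barcodes=2000,
                                       n_null_barcodes=500, seed=11)
        res = ambient_test(matrix, ambient_max=100, fdr=0.01, n_iters=500,
                           seed=11)
        rate = len(res.retained) / 500
        se = np.sqrt(0.01 * 0.99 / 500)
        assert rate <= 0.01 + 3 * se

    def test_concentrated_barcode_retained(self, rng):
        # ambient soup over genes 0..49; barcode with all mass on gene 50
        dense = np.zeros((51, 201), dtype=int)
        for j in range(200):
            dense[:50, j] = rng.multinomial(60, np.full(50, 0.02))
        dense[50, 200] = 500
        res = ambient_test(_matrix_from_dense(dense), ambient_max=100,
                           fdr=0.01, n_iters=500, seed=0)
        assert "B200" in res.retained

    def test_fdr_zero_retains_nothing(self, rng):
        dense = np.zeros((20, 60), dtype=int)
        for j in range(50):
            dense[:, j] = rng.multinomial(40, np.full(20, 0.05))
        for j in range(50, 60):
            dense[:, j] = rng.multinomial(400, np.full(20, 0.05))
        res = ambient_test(_matrix_from_dense(dense), fdr=0.0, n_iters=200,
                           seed=0)
        assert res.retained == set()

    def test_no_ambient_barcodes_errors(self):
        dense = np.full((5, 4), 100)
        with pytest.raises(ValueError, match="ambient_max"):
            ambient_test(_matrix_from_dense(dense), ambient_max=10)

    def test_same_seed_identical(self, rng):
        dense = rng.poisson(3, size=(30, 80))
        m = _matrix_from_dense(dense)
        r1 = ambient_test(m, ambient_max=100, n_iters=200, seed=7)
        r2 = ambient_test(m, ambient_max=100, n_iters=200, seed=7)
        assert (r1.pvalues == r2.pvalues).all()
        assert r1.retained == r2.retained


class TestChainDoubletFilter:
    def test_two_distinct_trb_excluded(self):
        contigs = [make_contig("BC1", "TRB", cdr3="CASSAF"),
                   make_contig("BC1", "TRB", cdr3="CASSBF")]
        assert chain_doublet_filter(contigs) == set()

    def test_one_trb_two_tra_kept(self):
        contigs = [make_contig("BC1", "TRB"),
                   make_contig("BC1", "TRA", cdr3="CAVAF"),
                   make_contig("BC1", "TRA", cdr3="CAVBF")]
        assert chain_doublet_filter(contigs) == {"BC1"}

    def test_duplicate_contig_rows_count_once(self):
        contigs = [make_contig("BC1", "TRB", umis=3),
                   make_contig("BC1", "TRB", umis=9)]  # same triple
        assert chain_doublet_filter(contigs) == {"BC1"}

    def test_contigless_barcodes_pass_via_universe(self):
        contigs = [make_contig("BC1", "TRB", cdr3="CASSAF"),
                   make_contig("BC1", "TRB", cdr3="CASSBF")]
        kept = chain_doublet_filter(contigs, barcodes={"BC1", "BC2"})
        assert kept == {"BC2"}


@pytest.fixture(scope="module")
def experiment():
    return simulate_experiment(n_real_cells=300, n_ambient_barcodes=2000,
                               doublet_rate=0.05, seed=5)


class TestCascade:
    def test_stage_counts_non_increasing(self, experiment):
        matrix, contigs, _, _ = experiment
        rep = run_qc_cascade(matrix, contigs,
                             QCConfig(ambient_iters=200, seed=5))
        kept = rep.stages["kept"].to_numpy()
        assert (np.diff(kept) <= 0).all()
        assert len(rep.kept_barcodes) == kept[-1]

    def test_disabled_stages_keep_everything(self, experiment):
        matrix, contigs, _, _ = experiment
        rep = run_qc_cascade(matrix, contigs, QCConfig(
            ambient_enabled=False, knee_enabled=False, mad_enabled=False,
            doublet_enabled=False))
        assert rep.kept_barcodes == matrix.barcodes

    def test_same_seed_identical_report(self, experiment):
        matrix, contigs, _, _ = experiment
        cfg = QCConfig(ambient_iters=200, seed=9)
        r1 = run_qc_cascade(matrix, contigs, cfg)
        r2 = run_qc_cascade(matrix, contigs, cfg)
        assert r1.kept_barcodes == r2.kept_barcodes
        assert r1.stages.equals(r2.stages)

    def test_doublet_exclusion_rate_matches_truth(self, experiment):
        matrix, contigs, _, truth = experiment
        detectable = {b for b, v in truth.detectable_doublet.items() if v}
        real = [b for b, v in truth.real_cell_flags.items() if v]
        kept = chain_doublet_filter(contigs, barcodes=real)
        excluded = set(real) - kept
        assert excluded == detectable


def test_qc_metrics_mito_fraction():
    dense = np.array([[4, 0], [6, 10]])  # gene 0 mitochondrial
    metrics = compute_qc_metrics(_matrix_from_dense(dense, mito_rows=[0]))
    assert metrics.loc["B0", "mito_fraction"] == pytest.approx(0.4)
    assert metrics.loc["B1", "n_genes"] == 1
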