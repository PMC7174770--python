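import numpy as np
import pytest

from repdiv.io import ContigRecord


def make_contig(barcode, chain, v="SYNTRBV1", cdr3="CASSLGQAYEQYF",
                j="SYNTRBJ1", productive=True, umis=5):
    return ContigRecord(barcode=barcode, chain=chain, v_gene=v, j_gene=j,
                        cdr3_aa=cdr3, productive=productive, umis=umis)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def paired_cell_contigs():
    """Three cells of two clones: one expanded (2 cells) + one singleton."""
    return [
        make_contig("BC1", "TRA", v="SYNTRAV1", cdr3="CAVRDF", j="SYNTRAJ1"),
        make_contig("BC1", "TRB", v="SYNTRBV1", cdr3="CASSAF", j="SYNTRBJ1"),
        make_contig("BC2", "TRA", v="SYNTRAV1", cdr3="CAVRDF", j="SYNTRAJ1"),
        make_contig("BC2", "TRB", v="SYNTRBV1", cdr3="CASSAF", j="SYNTRBJ1"),
        make_contig("BC3", "TRA", v="SYNTRAV2", cdr3="CAVKGF", j="SYNTRAJ2"),
        make_contig("BC3", "TRB", v="SYNTRBV2", cdr3="CASSBF", j="SYNTRBJ2"),
    ]
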