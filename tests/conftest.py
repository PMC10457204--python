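import io

import pytest

from clonolink import contig_io, synthetic_data as sd


def make_chain(locus, v, j, cdr3_nt, cdr3_aa, umis=1):
    return contig_io.Chain(locus=locus, v_gene=v, j_gene=j, cdr3_nt=cdr3_nt,
                           cdr3_aa=cdr3_aa, umis=umis)


def make_cell(barcode, alphas=(), betas=(), donor="d1", tissue="blood"):
    return contig_io.Cell(
        barcode=barcode,
        alpha_chains=list(alphas),
        beta_chains=list(betas),
        donor=donor,
        tissue=tissue,
    )


def pipeline_cells(contigs, meta, population="MAIT"):
    """contig table DataFrame -> gated cells, via the CSV round trip."""
    buf = io.StringIO(contigs.to_csv(index=False))
    records = contig_io.filter_contigs(contig_io.read_contig_table(buf))
    cells, n_doublets = contig_io.assemble_cells(records, meta.set_index("barcode"))
    return contig_io.gate_cells(cells, population), n_doublets


@pytest.fixture(scope="session")
def clean_repertoire():
    """Small noiseless repertoire: no dropout, no doublets, full capture."""
    cfg = sd.RepertoireConfig(
        seed=11, donors=2, clones_per_donor=60, cells_per_sample=400,
        dropout=0.0, doublet_rate=0.0, capture_rate=1.0,
    )
    return sd.generate_repertoire(cfg)


@pytest.fixture(scope="session")
def clean_cells(clean_repertoire):
    contigs, meta, truth = clean_repertoire
    cells, _ = pipeline_cells(contigs, meta)
    return cells, truth
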