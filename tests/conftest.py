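import pytest

import polwave as pw


@pytest.fixture(scope="session")
def small_cohort():
    """50 genes at a constant 3 kb/min with default noise, seeded."""
    cfg = pw.SimulationConfig(n_genes=50, rate_model=3.0, seed=11)
    genes = pw.simulate_annotation(cfg)
    truth = pw.make_ground_truth(genes, cfg)
    return cfg, genes, truth


@pytest.fixture(scope="session")
def count_cohort():
    """100 genes with a non-unity spike-in factor and grouped m6A truths."""
    cfg = pw.SimulationConfig(n_genes=100, spike_in_true_factor=0.7, seed=13)
    genes = pw.simulate_annotation(cfg)
    truth = pw.make_ground_truth(genes, cfg)
    tables = pw.simulate_count_tables(genes, truth, cfg)
    return cfg, genes, truth, tables


def make_gene(gene_id="g", chrom="chr1", strand="+", start=1000, end=21000, exons=None):
    tss, tts = (start, end) if strand == "+" else (end, start)
    return pw.GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, tss=tss, tts=tts,
        exons=tuple(exons) if exons else (),
    )
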