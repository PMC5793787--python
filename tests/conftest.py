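import pytest

from splicecloud import simulate
from splicecloud.annotation import GeneModel, Transcript


TOY_GTF = """\
chr1\ttest\tgene\t1\t500\t.\t+\t.\tgene_id "TOY"; gene_type "protein_coding";
chr1\ttest\ttranscript\t1\t500\t.\t+\t.\tgene_id "TOY"; transcript_id "TOY.inc";
chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "TOY"; transcript_id "TOY.inc";
chr1\ttest\texon\t201\t300\t.\t+\t.\tgene_id "TOY"; transcript_id "TOY.inc";
chr1\ttest\texon\t401\t500\t.\t+\t.\tgene_id "TOY"; transcript_id "TOY.inc";
chr1\ttest\ttranscript\t1\t500\t.\t+\t.\tgene_id "TOY"; transcript_id "TOY.skip";
chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "TOY"; transcript_id "TOY.skip";
chr1\ttest\texon\t401\t500\t.\t+\t.\tgene_id "TOY"; transcript_id "TOY.skip";
"""


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


def build_gene(gene_id, transcripts, chrom="chr1", strand="+", biotype="protein_coding",
               cds=None):
    """Construct a GeneModel from {tx_id: [exon intervals]} dicts."""
    gene = GeneModel(gene_id, chrom, strand, biotype)
    for tx_id, exons in transcripts.items():
        tx = Transcript(tx_id, sorted(exons), chrom, strand)
        if cds and tx_id in cds:
            tx.cds = sorted(cds[tx_id])
        gene.transcripts.append(tx)
    return gene


@pytest.fixture(scope="session")
def small_dataset():
    """A small coordinated dataset shared across tests (positive OR)."""
    cfg = simulate.SimConfig(
        n_genes=4, molecules_per_gene=400, odds_ratio=8.0,
        n_droplets=40_000, reads_per_molecule=15.0,
        unspliced_fraction=0.2, seed=11,
    )
    evidence, genes, truth = simulate.simulate_dataset(cfg)
    return cfg, evidence, genes, truth
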