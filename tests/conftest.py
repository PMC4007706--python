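import numpy as np
import pytest

from txsnp.models import Genome, GeneModel, SupercontigSeq, TranscriptModel
from txsnp.pipeline import PipelineConfig, run_stages
from txsnp.simulate import SimulationConfig, simulate, write_bundle

SIM_SEED = 20260417


@pytest.fixture(scope="session")
def sim():
    """Default-scale simulation shared by most suites."""
    return simulate(SimulationConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def bundle(sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    write_bundle(sim, outdir)
    return outdir


@pytest.fixture(scope="session")
def report(sim):
    cfg = PipelineConfig(strains=sim.config.strains)
    return run_stages(
        sim.genome, sim.genes, sim.sites, sim.tracks, sim.expression,
        sim.ntus, sim.ntu_fpkm, cfg,
    )


# A hand-built single-exon gene with fully known content:
#   offset 50 on the contig, 38-base transcript =
#   5'UTR "CCCCACGCCC" + CDS "ATGGAATACCATTGGTAA" + 3'UTR "GGGGGGGGGG"
TOY_OFFSET = 50
TOY_UTR5 = "CCCCACGCCC"
TOY_CDS = "ATGGAATACCATTGGTAA"
TOY_UTR3 = "GGGGGGGGGG"


@pytest.fixture
def toy():
    mrna = TOY_UTR5 + TOY_CDS + TOY_UTR3
    seq = "A" * TOY_OFFSET + mrna + "A" * 50
    genome = Genome.from_contigs([SupercontigSeq("chr", seq)])
    tx = TranscriptModel(
        transcript_id="toy_t1",
        gene_id="toy",
        contig_id="chr",
        strand="+",
        exons=((TOY_OFFSET, TOY_OFFSET + len(mrna)),),
        cds_intervals=(
            (TOY_OFFSET + len(TOY_UTR5), TOY_OFFSET + len(TOY_UTR5) + len(TOY_CDS)),
        ),
    )
    gene = GeneModel("toy", "chr", "+", (tx,))
    return genome, gene, tx


@pytest.fixture
def toy_spliced():
    """Two-exon plus-strand gene: exons (50,70) and (80,98), CDS (55,92)."""
    rng = np.random.default_rng(3)
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    seq = list("".join(bases[rng.integers(0, 4, 150)]))
    # transcript: utr5 5nt + CDS 27nt + utr3 6nt over exons 20nt + 18nt
    cds = "ATG" + "GAAGATCCTCAAGCTTTC" + "TTT" + "TAA"
    mrna = "CCCCC" + cds + "GGGGGG"
    exons = [(50, 70), (80, 98)]
    cursor = 0
    for s, e in exons:
        seq[s:e] = list(mrna[cursor : cursor + e - s])
        cursor += e - s
    genome = Genome.from_contigs([SupercontigSeq("chr", "".join(seq))])
    tx = TranscriptModel(
        transcript_id="sp_t1",
        gene_id="sp",
        contig_id="chr",
        strand="+",
        exons=tuple(exons),
        cds_intervals=((55, 70), (80, 92)),
    )
    return genome, GeneModel("sp", "chr", "+", (tx,)), tx
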