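import pytest

from cissage.annotation import Exon, GeneModel, GenomeAnnotation, Transcript
from cissage.synth import SimConfig, simulate_cohort


def make_gene(gid, chrom, strand, exon_coords, cds=None, symbol=None):
    exons = [Exon(chrom, s, e) for s, e in exon_coords]
    cds_start, cds_end = cds if cds else (None, None)
    t = Transcript(f"{gid}.t1", strand, exons, cds_start=cds_start, cds_end=cds_end)
    return GeneModel(id=gid, symbol=symbol or gid, chrom=chrom, strand=strand, transcripts=[t])


@pytest.fixture
def toy_ann():
    """Three '+' genes on chr1 (spans [100,1000), [2000,3000), [5000,6000))
    plus one gene on chr2: the worked example used across modules."""
    return GenomeAnnotation(
        [
            make_gene("G1", "chr1", "+", [(100, 400), (600, 1000)]),
            make_gene("G2", "chr1", "+", [(2000, 2300), (2500, 2700), (2800, 3000)]),
            make_gene("G3", "chr1", "+", [(5000, 5400), (5600, 6000)]),
            make_gene("H1", "chr2", "+", [(100, 500), (700, 900)]),
        ]
    )


@pytest.fixture
def toy_ann_minus_g2():
    """Same layout but G2 on the minus strand."""
    return GenomeAnnotation(
        [
            make_gene("G1", "chr1", "+", [(100, 400), (600, 1000)]),
            make_gene("G2", "chr1", "-", [(2000, 2300), (2500, 2700), (2800, 3000)]),
            make_gene("G3", "chr1", "+", [(5000, 5400), (5600, 6000)]),
        ]
    )


@pytest.fixture
def toy_ann_nested():
    """G2..G3 gap contains a nested antisense gene G4."""
    return GenomeAnnotation(
        [
            make_gene("G1", "chr1", "+", [(100, 400), (600, 1000)]),
            make_gene("G2", "chr1", "+", [(2000, 2300), (2500, 2700), (2800, 3000)]),
            make_gene("G3", "chr1", "+", [(5000, 5400), (5600, 6000)]),
            make_gene("G4", "chr1", "-", [(3500, 3800)]),
        ]
    )


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic study cohort (2,000 genes, 16 cis-SAGe + 23 decoys)."""
    return simulate_cohort(SimConfig(seed=17))


@pytest.fixture(scope="session")
def small_ann():
    """A small random annotation for oracle comparisons."""
    from cissage.synth import simulate_annotation

    return simulate_annotation(SimConfig(n_chromosomes=2, genes_per_chromosome=25, seed=5))
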