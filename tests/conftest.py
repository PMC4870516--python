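import numpy as np
import pytest

from isocoex.simulate import SimulationConfig


def gtf_line(chrom, start0, end0, strand, gene, tx):
    """One GTF exon line from 0-based half-open coordinates."""
    return (f"{chrom}\ttest\texon\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t"
            f'gene_id "{gene}"; transcript_id "{tx}";')


def build_gtf(exons):
    """exons: iterable of (chrom, start0, end0, strand, gene, tx)."""
    return "\n".join(gtf_line(*e) for e in exons) + "\n"


@pytest.fixture
def toy_event_gtf():
    """One gene, two transcripts, a genuine UA3E/AIDE pair on the + strand.

    Shared donor at 200; UA3E exon [300, 400) inside the long isoform's
    intron [200, 600); AIDE first exon [600, 700).
    """
    return build_gtf([
        ("chr1", 100, 200, "+", "g1", "g1.short"),
        ("chr1", 300, 400, "+", "g1", "g1.short"),
        ("chr1", 100, 200, "+", "g1", "g1.long"),
        ("chr1", 600, 700, "+", "g1", "g1.long"),
        ("chr1", 800, 850, "+", "g1", "g1.long"),
    ])


@pytest.fixture
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
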