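import numpy as np
import pytest

from wadjetscan.cluster_align import progressive_align
from wadjetscan.profile_search import Hit
from wadjetscan.refine_loop import run_pipeline
from wadjetscan.seq_io import ContigAnnotation, GeneRecord, GenomeSet
from wadjetscan.synthetic_data import ForgeSpec, forge_genomes, make_family_pools

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def family_pools():
    return make_family_pools(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def seed_alignments(family_pools):
    return {
        fam: progressive_align(sorted(family_pools[fam].items()))
        for fam in family_pools
    }


@pytest.fixture(scope="session")
def forge_bundle(family_pools):
    """(genomes, truth) for the full 10-case plan."""
    return forge_genomes(ForgeSpec(seed=FIXTURE_SEED), family_pools)


@pytest.fixture(scope="session")
def pipeline_result(seed_alignments, forge_bundle):
    """Six-iteration run on the 10-case forge fixture."""
    genomes, _ = forge_bundle
    return run_pipeline(seed_alignments, genomes, n_iter=6, seed=FIXTURE_SEED)


def make_contig(proteins_strands, contig_id="c1"):
    """Build a ContigAnnotation from (protein, strand) pairs."""
    genes = [
        GeneRecord(
            gene_id=f"{contig_id}_g{i:02d}",
            contig_id=contig_id,
            order_index=i,
            strand=strand,
            protein=protein,
        )
        for i, (protein, strand) in enumerate(proteins_strands)
    ]
    return ContigAnnotation(contig_id=contig_id, genes=genes)


def make_hits(contig, families):
    """Above-threshold Hit per (order_index -> family) mapping."""
    hits = {}
    for idx, fam in families.items():
        gene = contig.genes[idx]
        hits[gene.gene_id] = Hit(
            gene_id=gene.gene_id,
            family=fam,
            bit_score=100.0,
            query_span=(0, gene.length),
            above_threshold=True,
        )
    return hits


def single_contig_genome(contig, assembly_id="test_asm"):
    return GenomeSet(assembly_id=assembly_id, contigs=[contig])


def random_protein(rng: np.random.Generator, length: int) -> str:
    from wadjetscan._align import ALPHABET

    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))
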