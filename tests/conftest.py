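import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from poolvar.dtypes import GeneModel, GenomeSequence, VariantCall, reverse_complement

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def _mk_call(pos, ref, alt, contig="chr", pool="L", depth=100, alt_count=10):
    if len(ref) == 1 and len(alt) == 1:
        vtype = "SNV"
    elif len(alt) > len(ref):
        vtype = "insertion"
    else:
        vtype = "deletion"
    return VariantCall(
        contig_id=contig,
        pos=pos,
        ref=ref,
        alt=alt,
        vtype=vtype,
        depth=depth,
        alt_count=alt_count,
        var_freq=alt_count / depth,
        alt_fwd=alt_count // 2,
        alt_rev=alt_count - alt_count // 2,
        p_value=1e-6,
        pool_id=pool,
    )


@pytest.fixture
def make_call():
    """Factory for minimal VariantCall objects in annotation tests."""
    return _mk_call


# Toy layout used throughout the annotation tests:
#   gene1  +  CDS [1001, 1405]  ATG (GCT x130) GCG TGG TAT TAA
#   gene2  +  CDS [2001, 2300]  ATG (GGT x98) TAA
#   gene3  -  CDS [4001, 4300]  revcomp(ATG (CAT x98) TGA)
GENE1_CDS = "ATG" + "GCT" * 130 + "GCG" + "TGG" + "TAT" + "TAA"
GENE2_CDS = "ATG" + "GGT" * 98 + "TAA"
GENE3_CDS = "ATG" + "CAT" * 98 + "TGA"


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(11)
    seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 6000)]))
    assert len(GENE1_CDS) == 405 and len(GENE2_CDS) == 300
    seq[1000:1405] = list(GENE1_CDS)
    seq[2000:2300] = list(GENE2_CDS)
    seq[4000:4300] = list(reverse_complement(GENE3_CDS))
    genome = GenomeSequence(contig_id="chr", sequence="".join(seq))
    models = [
        GeneModel("gene1", "chr", 1001, 1405, "+"),
        GeneModel("gene2", "chr", 2001, 2300, "+"),
        GeneModel("gene3", "chr", 4001, 4300, "-"),
    ]
    return genome, models
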