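import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from m2acodon.codons import GeneCds, cytosolic_codon_set
from m2acodon.malc import TargetRna

# Reporter insert sequences (DNA as cloned; the package normalizes T->U).
S1 = "CAACGTCGCCGT"          # four m2A-dependent codons in tandem
S2 = "CAGCGTCAACAA"          # four in tandem
S3 = "CAACAGCGTCAACAACAG"    # six in tandem
S4 = "GTGGTGACAACA"          # none in the set


@pytest.fixture(scope="session")
def cyto_set():
    return cytosolic_codon_set()


@pytest.fixture
def rng():
    return np.random.default_rng(20240203)


def random_gene(rng, n_codons, codons, gene_id="g"):
    idx = rng.integers(0, len(codons), size=n_codons)
    return GeneCds(gene_id, "".join(codons[i] for i in idx))


@pytest.fixture
def toy_target():
    # 40-mer with the candidate adenosine at position 20
    seq = "GCGCGCGCGCUAACGGAUCACGAACGGCUAGCAAGGCUAG"
    return TargetRna("toy", seq, 20)
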