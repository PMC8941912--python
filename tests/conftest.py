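import numpy as np
import pytest

from mockqc.amplicon_analysis import PrimerPair, extract_amplicons, revcomp
from mockqc.compositional_stats import Composition
from mockqc.reference_data import load_reference
from mockqc.synthetic_data import make_genome


@pytest.fixture(scope="session")
def dna_ref():
    return load_reference(community="dna")


@pytest.fixture(scope="session")
def cell_ref():
    return load_reference(community="cell")


@pytest.fixture(scope="session")
def primers():
    return PrimerPair()


#: concrete resolutions of the degenerate primer parts used to build
#: synthetic 16S genes (Y->C, M->A forward; N->T, V->G, W->A reverse)
FW_SITE = "GTGCCAGCAGCCGCGGTAA"
RV_SITE = "GGACTACTGGGGTATCTAAT"


@pytest.fixture(scope="session")
def amplicon_fixture(cell_ref, primers):
    """Four strains with synthetic 16S genes and known V4 inserts."""
    strains = list(cell_ref.strain_ids[:4])
    inserts = {s: make_genome(250, 0.5, seed=10 + i) for i, s in enumerate(strains)}
    genes = {
        s: [
            make_genome(80, 0.5, seed=100 + i)
            + FW_SITE
            + inserts[s]
            + revcomp(RV_SITE)
            + make_genome(70, 0.5, seed=200 + i)
        ]
        for i, s in enumerate(strains)
    }
    refs = extract_amplicons(genes, primers, ref=cell_ref)
    comp = Composition(tuple(strains), np.array([30.0, 30.0, 20.0, 20.0]))
    return {"strains": strains, "inserts": inserts, "genes": genes, "refs": refs, "composition": comp}
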