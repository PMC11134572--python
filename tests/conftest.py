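import numpy as np
import pytest

from itempop import (
    AssessmentGrid,
    BackgroundFrequencies,
    HitThresholds,
    load_reference_frequencies,
)
from itempop.simulate import (
    PlantedEpitope,
    PlantedTregitope,
    SimSpec,
    generate_pssm_set,
    plant_protein,
)


@pytest.fixture(scope="session")
def uniform_bg():
    return BackgroundFrequencies.uniform()


@pytest.fixture(scope="session")
def pssm_set4():
    return generate_pssm_set(4, seed=7)


@pytest.fixture(scope="session")
def reference_tables():
    """Packaged Japanese/Caucasian carrier-frequency tables (Caucasian first)."""
    tables = load_reference_frequencies()
    return sorted(tables, key=lambda t: t.population)


@pytest.fixture(scope="session")
def planted_case(pssm_set4):
    """One protein with two planted epitopes, the second inside a Tregitope."""
    alleles = [p.allele for p in pssm_set4]
    spec = SimSpec(
        seed=11,
        n_alleles=4,
        protein_length=150,
        epitopes=[
            PlantedEpitope(alleles[0], 40, 2.5),
            PlantedEpitope(alleles[1], 90, 2.0),
        ],
        tregitopes=[PlantedTregitope("TRG1", 86, 15)],
    )
    protein, truth, registry = plant_protein(spec, pssm_set4)
    return {
        "spec": spec,
        "protein": protein,
        "truth": truth,
        "registry": registry,
        "pssms": pssm_set4,
        "alleles": alleles,
    }


def make_grid(z, alleles=None, masked=None, protein_id="toy"):
    """Assessment grid straight from a Z matrix (hits at the 1.64 tier)."""
    z = np.asarray(z, dtype=float)
    f, k = z.shape
    t = HitThresholds()
    hit_class = np.zeros(z.shape, dtype=np.int8)
    hit_class[z >= t.likely] = 1
    hit_class[z >= t.hit] = 2
    return AssessmentGrid(
        protein_id=protein_id,
        frames=np.arange(1, f + 1),
        alleles=alleles or [f"DRB1*{90 + j}:01" for j in range(k)],
        z=z,
        hit_class=hit_class,
        masked=np.zeros(f, dtype=bool) if masked is None else np.asarray(masked, bool),
        thresholds=t,
    )
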