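import pytest
from hypothesis import HealthCheck, settings

import coevmi as cv
from coevmi.structure_contacts import (
    SYNTHETIC_CHAIN_MAP_CANONICAL,
    SYNTHETIC_CHAIN_MAP_COMPENSATORY,
    build_synthetic_interface_pair,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def toy_alignment() -> cv.OrthologAlignment:
    return cv.OrthologAlignment(
        "PROT",
        [
            ("HUMAN", "MKT-LV"),
            ("MOUSE", "MKTALV"),
            ("RAT", "MRTALI"),
        ],
    )


@pytest.fixture
def small_complex() -> cv.SyntheticComplex:
    """Two proteins, one perfectly coupled planted pair, modest size."""
    spec = cv.SimulationSpec(
        n_species=80,
        proteins=[("A", 6), ("B", 6)],
        planted_pairs=[cv.PlantedPair("A", 2, "B", 5, 1.0)],
        substitution_prob=0.3,
        gap_prob=0.02,
        seed=11,
    )
    return cv.simulate_complex(spec)


@pytest.fixture(scope="session")
def interface_models(tmp_path_factory):
    """Synthetic canonical/compensatory interface structures, loaded."""
    d = tmp_path_factory.mktemp("structures")
    can_text, comp_text = build_synthetic_interface_pair()
    can_path = d / "canonical.pdb"
    comp_path = d / "compensatory.pdb"
    can_path.write_text(can_text)
    comp_path.write_text(comp_text)
    canonical = cv.load_structure(can_path, chain_map=SYNTHETIC_CHAIN_MAP_CANONICAL)
    compensatory = cv.load_structure(
        comp_path, chain_map=SYNTHETIC_CHAIN_MAP_COMPENSATORY
    )
    return canonical, compensatory
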