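import numpy as np
import pytest

from phagering import markers, synthetic


@pytest.fixture(scope="session")
def profiles():
    """Packaged marker profiles, calibrated once per session."""
    return list(markers.load_packaged_profiles())


SMALL_CFG = synthetic.CommunityConfig(
    n_phage_circular=6,
    n_plasmid_circular=2,
    n_linear_fragment=3,
    phage_length_range=(8_000, 15_000),
    plasmid_length_range=(5_000, 8_000),
    linear_length_range=(3_500, 6_000),
    n_recoded=2,
    dgr_specs=(synthetic.DgrSpec(vr_distance_from_rt=3_000),),
    spacer_specs={"Bacteroides": (3, 1), "Prevotella": (2, 1)},
    seed=11,
)


@pytest.fixture(scope="session")
def small_community():
    """A compact community exercising every planted feature."""
    contigs, truth = synthetic.generate_community(SMALL_CFG)
    return contigs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
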