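import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from nucorg import MB_PRESET, MT_PRESET, NucleusModel, simulate_nuclei
from nucorg.pipeline import generate_fixture
from nucorg.simulate import ExpressionSimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere():
    return NucleusModel.parametric("sphere", (0, 0, 0), (5.0, 5.0, 5.0))


@pytest.fixture
def ellipsoid_642():
    return NucleusModel.parametric("e642", (0, 0, 0), (6.0, 4.0, 2.0))


def random_ellipsoid(rng, nucleus_id="rand"):
    """Random non-degenerate ellipsoid with a random proper rotation."""
    axes = np.sort(rng.uniform(1.5, 7.0, size=3))[::-1]
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    from scipy.spatial.transform import Rotation

    return NucleusModel.parametric(
        nucleus_id, rng.uniform(-5, 5, size=3), axes, Rotation.from_quat(q).as_matrix()
    )


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """Small synthetic study shared by pipeline/CLI tests."""
    out = tmp_path_factory.mktemp("study") / "fix"
    generate_fixture(
        out,
        seed=7,
        n_per_group=30,
        expression_config=ExpressionSimConfig(
            n_genes=3000,
            chromosome_lengths_bp={
                "chr1": 248_956_422, "chr2": 242_193_529, "chr11": 135_086_622,
                "chr12": 133_275_309, "chr16": 90_338_345, "chr17": 83_257_441,
                "chrX": 156_040_895,
            },
        ),
    )
    return out


@pytest.fixture(scope="session")
def mb_population():
    return simulate_nuclei(200, MB_PRESET, seed=11)


@pytest.fixture(scope="session")
def mt_population():
    return simulate_nuclei(200, MT_PRESET, seed=12)
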