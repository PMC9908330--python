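import numpy as np
import pytest
import trimesh

from rssm.mesh import TriangleMesh
from rssm.synthetic import PopulationConfig, build_template, sample_population


@pytest.fixture(scope="session")
def tetrahedron() -> TriangleMesh:
    v = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                  [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f, name="tetra")


from rssm.synthetic import icosphere_like as icosphere  # noqa: E402


@pytest.fixture(scope="session")
def sphere2() -> TriangleMesh:
    return icosphere(2.0, 3)


@pytest.fixture(scope="session")
def torus() -> TriangleMesh:
    tm = trimesh.creation.torus(major_radius=10.0, minor_radius=3.0,
                                major_sections=48, minor_sections=24)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                        name="torus")


@pytest.fixture(scope="session")
def template() -> TriangleMesh:
    return build_template((24, 16))


@pytest.fixture(scope="session")
def default_cohort():
    """The default 31-subject synthetic study cohort."""
    return sample_population(PopulationConfig())


@pytest.fixture(scope="session")
def clean_cohort():
    """31 subjects, no noise and no misalignment: pure latent-mode shapes."""
    cfg = PopulationConfig(vertex_noise_sd=0.0, misalign_rotation_sd=0.0,
                           misalign_translation_sd=0.0)
    return sample_population(cfg)
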