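import numpy as np
import pytest

from toothssm.elastic import RegistrationParams, two_pass_register
from toothssm.model import fit_model
from toothssm.primitives import make_cube, make_icosphere
from toothssm.synth import (GroupSpec, PopulationSpec, ToothParams,
                            cohort_from_specimens, enamel_submesh,
                            generate_population, generate_tooth)

SMALL_RES = (36, 42)


@pytest.fixture(scope="session")
def unit_cube():
    return make_cube(1.0)


@pytest.fixture(scope="session")
def icosphere2():
    return make_icosphere(radius=2.0, subdivisions=4)


@pytest.fixture(scope="session")
def default_tooth():
    """Noise-free tooth at default parameters (mesh + material labels)."""
    return generate_tooth(ToothParams())


@pytest.fixture(scope="session")
def small_params():
    return ToothParams(mesh_resolution=SMALL_RES)


@pytest.fixture(scope="session")
def population6(small_params):
    spec = PopulationSpec(groups=(GroupSpec("A", 6, small_params),),
                          param_cv=0.05, noise_amplitude=0.05, seed=1)
    return generate_population(spec)


@pytest.fixture(scope="session")
def dissimilar_baseline():
    """An arbitrary baseline tooth unlike the test population, mirroring the
    use of a single (unrepresentative) specimen as the initial template."""
    params = ToothParams(crown_length=9, root_length=19, md_diameter_crown=6.5,
                         ll_diameter_crown=7.2, md_diameter_cervix=5.0,
                         ll_diameter_cervix=6.4, root_curvature=2.5,
                         apex_taper=2.2, mesh_resolution=SMALL_RES)
    mesh, _ = generate_tooth(params)
    return mesh


@pytest.fixture(scope="session")
def registered6(population6, dissimilar_baseline):
    training = [(s.mesh, enamel_submesh(s.mesh, s.material)) for s in population6]
    with pytest.warns(UserWarning):
        return two_pass_register(training, dissimilar_baseline, RegistrationParams(),
                                 ids=[s.id for s in population6],
                                 groups=[s.group for s in population6])


@pytest.fixture(scope="session")
def mode_population():
    """n = 30 population with two independent generative modes (overall scale
    and crown:root ratio) at CV 0.1 and 0.02 mm surface noise."""
    spec = PopulationSpec(groups=(GroupSpec("A", 30, ToothParams(mesh_resolution=(32, 40))),),
                          scale_cv=0.1, ratio_cv=0.1, noise_amplitude=0.02, seed=7)
    return generate_population(spec)


@pytest.fixture(scope="session")
def mode_cohort(mode_population):
    return cohort_from_specimens(mode_population)


@pytest.fixture(scope="session")
def mode_model(mode_cohort):
    return fit_model(mode_cohort)
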