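import numpy as np
import pytest

import chrysokin as ck


@pytest.fixture(scope="session")
def params():
    return ck.ModelParams.default()


@pytest.fixture(scope="session")
def standard_initial():
    return ck.SpeciesState(C_EDA=0.02, C_DMH=0.022)


@pytest.fixture(scope="session")
def traj_130(params, standard_initial):
    """Batch trajectory at 130 degC, standard loadings, 60 s window."""
    t_eval = np.linspace(0.0, 60.0, 121)
    return ck.simulate_batch(standard_initial, params, 403.15, 60.0,
                             t_eval=t_eval)


@pytest.fixture(scope="session")
def noiseless_tables(params):
    """Noise-free synthetic tables of the full three-series design."""
    designs = ck.paper_design(noise_sd=0.0)
    return [t for d in designs for t in ck.generate_dataset(d, params)]


@pytest.fixture(scope="session")
def perturbed_init(params):
    """A deliberately wrong starting guess: pre-exponentials off by 2-3x,
    activation energies off by 3-5 kJ/mol."""
    from dataclasses import replace

    pert = {
        name: ck.ArrheniusLaw(A=law.A * factor, Ea=law.Ea + shift)
        for (name, law), factor, shift in zip(
            params.arrhenius_laws.items(), (3.0, 1 / 3, 2.0, 0.5),
            (5.0, -5.0, 3.0, -3.0))
    }
    return replace(params, arrhenius_laws=pert)


@pytest.fixture(scope="session")
def noiseless_joint_fit(noiseless_tables, perturbed_init):
    """Two-stage fit of the full noiseless design from the perturbed guess."""
    return ck.joint_fit(noiseless_tables, perturbed_init, ck.FitOptions())


@pytest.fixture(scope="session")
def noisy_global_fit(params, perturbed_init):
    """Global Arrhenius fit on sd=0.01 triplicate data, fixed seed."""
    designs = ck.paper_design(noise_sd=0.01, seed=42)
    tables = [t for d in designs for t in ck.generate_dataset(d, params)]
    return ck.joint_fit(tables, perturbed_init, ck.FitOptions(), mode="global")
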