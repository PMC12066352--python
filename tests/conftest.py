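import numpy as np
import pytest

import nettemp as nt


def random_params(rng: np.random.Generator, p: int,
                  encoding: nt.Encoding = nt.Encoding.PM1,
                  beta: float | None = None) -> nt.IsingParameters:
    """Random small Ising parameters for property tests."""
    omega = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    omega[iu] = rng.normal(0, 0.4, iu[0].size)
    omega = omega + omega.T
    tau = rng.normal(0, 0.5, p)
    b = beta if beta is not None else float(rng.uniform(0.2, 3.0))
    return nt.IsingParameters(omega, tau, b, encoding)


@pytest.fixture(scope="session")
def recovery_panels():
    """Four-wave cohort from the recovery design (moderate n for speed)."""
    design = nt.recovery_design(seed=42, n_per_wave=5000)
    return design, nt.generate_longitudinal(design)


@pytest.fixture(scope="session")
def recovery_fit(recovery_panels):
    _, panels = recovery_panels
    return nt.fit_multigroup(panels,
                             nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_EDGES))
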