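import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    # fixtures used under @given are immutable specs; reuse is safe
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture()
def zero_equation():
    from onesitebf.equations import EquationSpec

    return EquationSpec(
        name="zero", intercept_male=0, coef_mass_male=0, coef_circ_male=0,
        intercept_female=0, coef_mass_female=0, coef_circ_female=0,
        mass_unit="kg", circ_unit="cm",
    )


@pytest.fixture()
def imperial_equation():
    """Synthetic imperial-unit equation used in worked examples."""
    from onesitebf.equations import EquationSpec

    return EquationSpec(
        name="synthetic-imperial",
        intercept_male=10, coef_mass_male=0, coef_circ_male=0,
        intercept_female=-30, coef_mass_female=-0.1, coef_circ_female=2.0,
        mass_unit="lb", circ_unit="in",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded noisy cohort (truth + observed), 60 subjects, session-cached."""
    from onesitebf.synthcohort import CohortConfig, simulate_cohort

    cfg = CohortConfig(n_total=60, n_female=30, n_male=30, seed=42)
    truth, observed = simulate_cohort(cfg)
    return cfg, truth, observed


@pytest.fixture(scope="session")
def noiseless_cohort():
    from onesitebf.synthcohort import CohortConfig, simulate_cohort

    cfg = CohortConfig(n_total=60, n_female=30, n_male=30, seed=7).noiseless()
    truth, observed = simulate_cohort(cfg)
    return cfg, truth, observed
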