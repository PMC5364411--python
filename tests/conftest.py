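import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crosstrait as ct
from crosstrait.types import CohortDesign, GeneticArchitecture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_panel():
    """200-haplotype, 400-variant reference panel with ~16 LD blocks."""
    return ct.simulate_reference_panel(200, 400, 25, seed=1)


@pytest.fixture(scope="session")
def small_scores(small_panel):
    return ct.compute_ld_scores(small_panel, window_cm=1.0)


@pytest.fixture(scope="session")
def desk_arch():
    """Desk-scale architecture: strong signal, common disease, for cohort tests."""
    return GeneticArchitecture(
        h2_liab_1=0.3, h2_liab_2=0.3, r_g=0.5, K_1=0.2, K_2=0.2, prop_causal=0.2
    )


@pytest.fixture(scope="session")
def desk_effects(desk_arch, small_panel):
    return ct.draw_effect_sizes(desk_arch, small_panel.variants, seed=2)


@pytest.fixture(scope="session")
def desk_cohort(small_panel, desk_effects, desk_arch):
    design = CohortDesign(n_cases_1=300, n_controls_1=400)
    return ct.simulate_liability_cohort(
        small_panel, desk_effects, desk_arch, design, 1, seed=3
    )


@pytest.fixture(scope="session")
def marginal_discovery(small_panel, desk_effects):
    """Trait-2 discovery summary statistics from the marginal-effect model."""
    H = small_panel.haplotypes.astype(float)
    X = (H - H.mean(0)) / H.std(0)
    R = (X.T @ X) / H.shape[0]
    n2 = 50_000
    rng = np.random.default_rng(4)
    bhat = R @ desk_effects["beta2"].to_numpy() + rng.standard_normal(
        len(small_panel.variants)
    ) / np.sqrt(n2)
    return ct.SummaryStats.from_z(
        small_panel.variants, bhat * np.sqrt(n2), float(n2), beta=bhat
    )
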