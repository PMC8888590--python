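import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from glycoscreen import SimulationConfig, NoiseConfig, generate_screen, summarize_genes


NO_NOISE = NoiseConfig(count_cv=0.0, absorbance_sd=0.0, plate_offset_sd=0.0,
                       curve_absorbance_sd=0.0)


@pytest.fixture(scope="session")
def small_screen():
    """2-plate screen with all planted classes and realistic noise."""
    cfg = SimulationConfig(
        n_plates=2,
        seed=11,
        class_fractions={
            "neutral": 0.80,
            "lethal": 0.05,
            "glycolysis_low": 0.05,
            "vem_enhancer_lactate": 0.05,
            "vem_enhancer_viability": 0.05,
        },
    )
    ds, truth = generate_screen(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def zero_noise_neutral_screen():
    """1-plate, all-neutral, zero-noise screen: every FC must be exactly 1."""
    cfg = SimulationConfig(n_plates=1, seed=3, class_fractions={"neutral": 1.0},
                           noise=NO_NOISE)
    ds, truth = generate_screen(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def small_summary(small_screen):
    _, ds, _ = small_screen
    return summarize_genes(ds)
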