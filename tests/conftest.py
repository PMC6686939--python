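import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from tillseq import AmpliconPanel, Amplicon, build_design, make_fixture


@pytest.fixture
def small_panel() -> AmpliconPanel:
    return AmpliconPanel(
        (
            Amplicon.from_sequence("AMP_A", "ATGC" * 25),
            Amplicon.from_sequence("AMP_B", "GGCC" * 30),
            Amplicon.from_sequence("AMP_C", "ATAT" * 40),
        )
    )


@pytest.fixture
def design_3x16():
    return build_design(3, 16)


@pytest.fixture
def design_3x4():
    return build_design(3, 4)


@pytest.fixture(scope="session")
def toy_fixture():
    """One noise-free toy experiment shared across tests."""
    return make_fixture("toy", seed=11, error_rate=0.0)


@pytest.fixture(scope="session")
def paper_scale_fixture():
    """One defaults paper-shaped experiment (48 pools, 32 amplicons)."""
    return make_fixture("paper_scale", seed=7)
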