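import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def fig_family_alignment():
    """The worked two-sub-family example: 8 columns, red 2 rows / purple 3.

    Column 3 holds a gap majority in both sub-families (an insertion
    column); the purple consensus converts the (6,7) base pair of the red
    consensus into two unpaired columns.
    """
    from acm.io_formats import AnnotatedAlignment

    rows = [
        ("red", "r1", "GG-ACGCC"),
        ("red", "r2", "GG-ACGUC"),
        ("purple", "p1", "GG-ACAAC"),
        ("purple", "p2", "GGUACAGC"),
        ("purple", "p3", "GG-ACGAC"),
    ]
    structures = {"red": "<<**><>>", "purple": "<<**>**>"}
    return AnnotatedAlignment(rows, structures, 8)


@pytest.fixture(scope="session")
def trna_alignment():
    from acm.synthetic_fixtures import make_trna_like

    return make_trna_like(seed=11)


@pytest.fixture(scope="session")
def trna_model(trna_alignment):
    from acm.training import BuildConfig, build_model

    return build_model(trna_alignment, BuildConfig(seed=11))
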