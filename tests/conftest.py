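import pytest

from rlwm.cohort import CohortSpec, generate_cohort
from rlwm.task import TaskConfig, build_session


@pytest.fixture(scope="session")
def default_plan():
    return build_session(TaskConfig(), seed=123)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (12 per group, complete brain data) shared by the
    behavioral and brain-link tests."""
    spec = CohortSpec(
        n_young=12, n_older=12, n_missing_brain_young=0, n_missing_brain_older=0
    )
    return generate_cohort(spec, seed=42)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (36 young / 42 older)."""
    return generate_cohort(CohortSpec(), seed=7)
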