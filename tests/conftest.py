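import pytest

from mcamorph.cohort import default_table1_specs, generate_cohort
from mcamorph.pipeline import AnalysisConfig, run_full_analysis


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_table1_specs(), seed=1)


@pytest.fixture(scope="session")
def default_report(default_cohort):
    return run_full_analysis(default_cohort, AnalysisConfig())
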