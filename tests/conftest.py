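import pytest

from nmbia import base_case
from nmbia.cohort import (nmba_procedure_count, stratify, sugammadex_population,
                          total_annual_procedures)


@pytest.fixture(scope="session")
def base_params():
    return base_case()


def pipeline_strata(params):
    """Volumes -> NMBA count -> stratified counts with sugammadex filled."""
    total = total_annual_procedures(params.volumes)
    nmba = nmba_procedure_count(total, params.population.p_nmba)
    return sugammadex_population(stratify(nmba, params.population, params.mix),
                                 params.adoption)


@pytest.fixture(scope="session")
def base_strata(base_params):
    return pipeline_strata(base_params)
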