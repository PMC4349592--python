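"""Shared fixtures: the packaged template and a session-scoped reference
built from a 10-embryo synthetic wild-type cohort (expensive, built once)."""

import pytest

from lineascope.config import AnalysisConfig
from lineascope.experiments import wt_cohort
from lineascope.reference import build_reference
from lineascope.simulate import Template


@pytest.fixture(scope="session")
def template() -> Template:
    return Template.packaged()


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def wt10(template):
    return wt_cohort(template, 10, seed0=100)


@pytest.fixture(scope="session")
def ref10(wt10, config):
    return build_reference(wt10, config)
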