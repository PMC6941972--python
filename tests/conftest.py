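"""Shared fixtures: grammar, toy corpora, and the trained study pipeline.

The expensive fixtures (trained translator, recovery experiments) are
session-scoped so the acceptance tests share one pipeline run.
"""

from __future__ import annotations

import numpy as np
import pytest

from gexmol import experiments as ex
from gexmol import synthetic as syn
from gexmol.grammar import build_grammar


@pytest.fixture(scope="session")
def grammar():
    return build_grammar()


@pytest.fixture(scope="session")
def small_corpus():
    """The 200-molecule toy corpus used in the round-trip and translator runs."""
    return syn.make_corpus(200, "small", seed=7)


@pytest.fixture(scope="session")
def toy_translator():
    """200 molecules, 50 epochs — the small-corpus translator run."""
    return ex.toy_translator_experiment(seed=1)


@pytest.fixture(scope="session")
def study():
    """Reference synthetic world: corpus 500, 64 genes, noise 0.1, 20 queries."""
    return ex.study_data()


@pytest.fixture(scope="session")
def study_translator(study):
    corpus, _, _ = study
    return ex.study_translator(corpus)


@pytest.fixture(scope="session")
def recovery_reports(study, study_translator):
    """Stage-I conditional recovery over three seeds (stochastic criterion)."""
    return [
        ex.conditional_recovery_experiment(seed, translator=study_translator, data=study)
        for seed in (0, 1, 2)
    ]
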