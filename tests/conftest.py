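"""Shared fixtures: small deterministic objects plus two session-scoped
synthetic worlds (letters-driven and neighbor-driven pseudoword valence)
that the pipeline and acceptance tests analyse end-to-end."""

from __future__ import annotations

import pytest

from pseudovalence import pipeline
from pseudovalence.form_features import CleanLexicon


@pytest.fixture(scope="session")
def tiny_lexicon() -> CleanLexicon:
    return CleanLexicon(
        words=("bus", "bug", "cat", "vacation", "grawp"),
        valences=(5.0, 3.0, 7.0, 8.5, 4.2),
    )


@pytest.fixture(scope="session")
def letters_world() -> pipeline.SyntheticWorld:
    return pipeline.build_synthetic_world("letters", seed=7)


@pytest.fixture(scope="session")
def neighbor_world() -> pipeline.SyntheticWorld:
    return pipeline.build_synthetic_world("neighbor", seed=7)
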