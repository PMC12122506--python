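from __future__ import annotations

import numpy as np
import pytest

from faersig.ingest import assemble, deduplicate, select_primary_suspect
from faersig.synthetic import GeneratorConfig, SignalSpec, generate

TARGET_NAMES = ["vismodegib", "erivedge"]


def assemble_bundle(bundle):
    """Dedup + assemble a generated bundle into (all reports, target reports)."""
    demo = deduplicate(bundle.demo_rows)
    reports, _ = assemble(demo, bundle.drug_rows, bundle.reac_rows, bundle.ther_rows)
    target = select_primary_suspect(reports, TARGET_NAMES)
    return reports, target


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        n_cases=4000,
        n_drugs=10,
        n_events=40,
        n_socs=8,
        seed=11,
        signal_spec=[SignalSpec("pt_001", 12.0)],
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_db(small_bundle):
    """(all reports, target reports) for the small synthetic extract."""
    return assemble_bundle(small_bundle)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
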