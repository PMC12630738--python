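import numpy as np
import pytest
from hypothesis import settings

from spotsig import pipeline
from spotsig.synthetic import SimulationConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (50 spots/sample, ~1600 spots) for fast tests."""
    cfg = SimulationConfig(rng_seed=11, spots_per_sample=50)
    spots, counts, truth, metabolites, bulk = generate_cohort(cfg)
    return dict(config=cfg, spots=spots, counts=counts, truth=truth,
                metabolites=metabolites, bulk=bulk)


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    spots = pipeline.classify_spots(small_cohort["spots"])
    return pipeline.preprocess_cohort(small_cohort["counts"], spots)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default cohort scale (seed 1).

    Shared across tests that exercise the end-to-end behavior:
    simulate -> classify -> preprocess -> discover -> score -> group.
    """
    cfg = SimulationConfig(rng_seed=1)
    spots, counts, truth, metabolites, bulk = generate_cohort(cfg)
    classified = pipeline.classify_spots(spots)
    cohort = pipeline.preprocess_cohort(counts, classified)
    apc, ceg, records = pipeline.discover(
        cohort, panel=truth.planted_gland
    )
    scores = pipeline.score(
        cohort, {"APC_like": apc, "CEG_like": ceg}, seed=1
    )
    groups = pipeline.group(cohort, scores, metabolites=metabolites)
    return dict(config=cfg, spots=spots, counts=counts, truth=truth,
                metabolites=metabolites, bulk=bulk, cohort=cohort,
                apc=apc, ceg=ceg, records=records, scores=scores,
                groups=groups)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
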