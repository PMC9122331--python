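import pathlib

import pytest

from turnover_aging import estimation as est
from turnover_aging.kinetics import DEFAULT_POOL_PARAMS
from turnover_aging.synthetic import CohortConfig, EffectSpec, write_cohort


@pytest.fixture(scope="session")
def pool():
    return DEFAULT_POOL_PARAMS


@pytest.fixture(scope="session")
def noiseless_cohort(tmp_path_factory):
    """Small zero-noise cohort with injected effects, written to disk once."""
    cfg = CohortConfig(
        n_proteins=60, ratio_noise_cv=0.0, missing_rate=0.0, seed=42,
        effect_spec=EffectSpec(n_rll=5, n_rsl=5, extra_factor=1.5),
    )
    outdir = pathlib.Path(tmp_path_factory.mktemp("cohort"))
    paths = write_cohort(cfg, outdir)
    return cfg, paths


@pytest.fixture(scope="session")
def noiseless_courses(noiseless_cohort):
    cfg, paths = noiseless_cohort
    sm = est.read_sample_map(paths["sample_map"])
    courses, lfq = est.read_protein_groups(
        paths["proteinGroups_young_cortex_hom"], sm)
    return cfg, courses, lfq
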