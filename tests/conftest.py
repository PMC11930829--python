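import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cfmeth as cf
from cfmeth.types import MethylationMatrix, SampleMeta

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def mk_plasma(values, labels, site_ids=None, stages=None):
    """Hand-built plasma matrix: labels are 1 (cancer, PAC) / 0 (normal)."""
    values = np.asarray(values, dtype=float)
    if site_ids is None:
        site_ids = [f"g{j}" for j in range(values.shape[1])]
    metas = []
    for i, y in enumerate(labels):
        if y:
            stage = stages[i] if stages else "I"
            metas.append(SampleMeta(f"s{i:03d}", "plasma", "PAC", stage))
        else:
            metas.append(SampleMeta(f"s{i:03d}", "plasma", "normal", "NA"))
    return MethylationMatrix(values, metas, site_ids=list(site_ids))


def case_labels(matrix):
    return np.array([1 if s.is_cancer else 0 for s in matrix.samples])


@pytest.fixture(scope="session")
def config():
    return cf.default_config()


@pytest.fixture(scope="session")
def tissue_cohort(config):
    return cf.simulate_tissue_cohort(config, n_pairs=33)


@pytest.fixture(scope="session")
def discovery_cohort(config):
    return cf.simulate_plasma_cohort(config)


@pytest.fixture(scope="session")
def calibration_normals(config):
    matrix, _ = cf.simulate_plasma_cohort(
        config, n_cases_by_stage={}, n_controls=96, cohort_label="calibration"
    )
    return matrix


@pytest.fixture(scope="session")
def pac_panel(discovery_cohort):
    _, truth = discovery_cohort
    return cf.MarkerPanel("PAC", tuple(truth.planted_markers["PAC"]))
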