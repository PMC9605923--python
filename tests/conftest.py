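import numpy as np
import pandas as pd
import pytest

from amygate import GeneratorConfig, GatekeeperModel, generate_cohort
from amygate.cohort import Cohort, FOLLOWUP_COLUMNS, REGION_PREFIX
from amygate.config import ABETA_NEG, ABETA_POS

# small, fast search space used by most pipeline-level tests
FAST_KWARGS = dict(
    families=("KNN", "LR"),
    grids={"KNN": [{"n_neighbors": 5}], "LR": [{"C": 1.0}]},
    cv_folds=5,
)


@pytest.fixture(scope="session")
def base_cohort() -> Cohort:
    """Default-condition synthetic cohort, shared across tests."""
    return generate_cohort(GeneratorConfig(n_subjects=400, seed=7))


@pytest.fixture(scope="session")
def fitted_small(base_cohort):
    """A fast end-to-end fit on the shared cohort."""
    return GatekeeperModel(base_cohort, seed=1, **FAST_KWARGS).fit()


def make_cohort(
    n: int,
    n_regions: int = 4,
    seed: int = 0,
    labels=None,
    apoe=None,
    region_values=None,
    csf=None,
    followups=None,
) -> Cohort:
    """Hand-built cohort for targeted unit tests.

    Gold labels are realized through AV45 SUVr values on the correct side
    of the cutoff so the label-value invariant holds by construction.
    """
    rng = np.random.default_rng(seed)
    labels = (
        np.asarray(labels)
        if labels is not None
        else np.where(rng.random(n) < 0.5, ABETA_POS, ABETA_NEG)
    )
    apoe = np.asarray(apoe) if apoe is not None else rng.random(n) < 0.5
    region_names = [f"R{i:02d}" for i in range(n_regions)]
    data = {
        "subject_id": [f"T{i:04d}" for i in range(n)],
        "age": rng.normal(72, 7, n),
        "sex": (rng.random(n) < 0.5).astype(int),
        "apoe4": apoe,
        "tracer": ["AV45"] * n,
        "amyloid_suvr": np.where(labels == ABETA_POS, 1.4, 1.0),
        "csf_ab42": csf if csf is not None else [np.nan] * n,
        "astatus": labels,
    }
    if region_values is None:
        region_values = np.exp(rng.normal(np.log(1.25), 0.08, (n, n_regions)))
    for j, name in enumerate(region_names):
        data[REGION_PREFIX + name] = region_values[:, j]
    fups = (
        pd.DataFrame(followups, columns=FOLLOWUP_COLUMNS)
        if followups is not None
        else pd.DataFrame(columns=FOLLOWUP_COLUMNS)
    )
    return Cohort(pd.DataFrame(data), region_names, fups)
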