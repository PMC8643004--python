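import pytest
from hypothesis import HealthCheck, settings

import posturegrade as pg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def group_params():
    return pg.load_group_params()


@pytest.fixture(scope="session")
def cohort70():
    """One synthetic cohort at the reference group sizes."""
    return pg.generate_cohort(seed=2024)


def random_feasible_target(rng, params):
    """Random feature vector within +-3 SD of a random severity class,
    rejected into the geometrically realizable region."""
    while True:
        c = int(rng.integers(params.n_classes))
        vals = {}
        for f in pg.FEATURE_NAMES:
            mu, sd = params.means[f][c], params.sds[f][c]
            lo, hi = max(0.0, mu - 3 * sd), mu + 3 * sd
            vals[f] = float(rng.uniform(lo, hi))
        fv_kwargs = {f: min(vals[f], 179.0) for f in pg.FEATURE_NAMES}
        target = pg.FeatureVector(**fv_kwargs)
        if pg.feasible_target(target):
            return target
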