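import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic survey shared across tests (seed fixed)."""
    from reefbarrens import synthetic

    cfg = synthetic.DesignConfig(
        lines_per_site=2, line_length_m=38.0, image_spacing_m=0.4
    )
    return synthetic.simulate_dataset(design_config=cfg, seed=7)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    from reefbarrens import imagefilter

    df = imagefilter.classify_barrens(small_dataset["records"])
    df = imagefilter.filter_reef(df)
    df = imagefilter.subset_every_kth(df, 5)
    return imagefilter.build_analysis_table(df, small_dataset["rugosity"])


@pytest.fixture(scope="session")
def m1_fit(small_table):
    """Default-engine M1 fit on a well-identified redrawn outcome."""
    import warnings

    from scipy.special import expit

    from reefbarrens import stmodel

    df = small_table.df.copy()
    X, _ = stmodel.build_design_matrix(df)
    beta = np.array([-1.0, -0.8, 0.25, 0.5, -0.3, -0.7, 0.1])
    rng = np.random.default_rng(101)
    df["barren"] = (rng.random(len(df)) < expit(X @ beta)).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stmodel.fit(
            df, "M1", engine_config=stmodel.EngineConfig(seed=11)
        )


def flat_grid(value=20.0, shape=(9, 9), cell=1.0):
    from reefbarrens.terrain import BathymetryGrid

    return BathymetryGrid(np.full(shape, float(value)), cell)
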