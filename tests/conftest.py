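import numpy as np
import pytest

import chemocal as cc

ANALYTES = ["CFPM", "TAZO"]


@pytest.fixture(scope="session")
def grid():
    return cc.WavelengthGrid()


@pytest.fixture(scope="session")
def pure(grid):
    return cc.build_pure_spectra(grid=grid)


@pytest.fixture(scope="session")
def calib_design():
    return cc.generate_brereton()


@pytest.fixture(scope="session")
def y_cal(calib_design):
    return calib_design.to_concentration_table("cal")


@pytest.fixture(scope="session")
def x_cal_clean(pure, y_cal):
    return cc.simulate_mixtures(pure, y_cal, cc.NoiseModel(0.0))


@pytest.fixture(scope="session")
def x_cal_noisy(pure, y_cal):
    return cc.simulate_mixtures(pure, y_cal, cc.NoiseModel(0.002, seed=11))


@pytest.fixture(scope="session")
def validation_design(calib_design):
    cands = cc.enumerate_candidates(cc.DEFAULT_DOMAIN, 1.0, exclude=calib_design)
    design, _ = cc.fedorov_select(
        cands, 13, cc.InformationModel("quadratic", cc.DEFAULT_DOMAIN), seed=5
    )
    return design


@pytest.fixture(scope="session")
def default_report():
    """One full default-configuration pipeline run shared across tests."""
    return cc.run_pipeline(cc.RunConfig())


def mean_rmsep(report, model_name):
    return float(
        np.mean([report.metrics[model_name][a].rmse for a in ANALYTES])
    )
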