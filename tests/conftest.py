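import datetime as dt

import numpy as np
import pytest

from lingvar import DailyFeatureMatrix, FitConfig, make_toy_dictionary
from lingvar.simulate import chain_precision, default_temporal_matrix, simulate_gvar_series

START = dt.date(2020, 1, 6)


def make_matrix(values, user_id="u0", start=START, survey_date=None, word_count=None):
    """DailyFeatureMatrix on consecutive days starting at START."""
    values = np.asarray(values, dtype=float)
    dates = [start + dt.timedelta(days=i) for i in range(len(values))]
    return DailyFeatureMatrix(
        user_id=user_id,
        dates=dates,
        feature_names=[f"f{j}" for j in range(values.shape[1])],
        values=values,
        word_count=word_count,
        survey_date=survey_date,
    )


def simulated_matrix(B, K, T, seed=0, scale=3.0, user_id="u0"):
    """Matrix from a stationary GVAR draw mapped onto the percentage scale."""
    y = simulate_gvar_series(B, K, T, seed=seed)
    return make_matrix(100.0 / (1.0 + np.exp(-y / scale)), user_id=user_id)


@pytest.fixture
def toy_dict():
    return make_toy_dictionary()


@pytest.fixture
def unpenalised_config():
    return FitConfig(lambda_beta_values=(0.0,), lambda_kappa_values=(0.0,))


@pytest.fixture
def chain9():
    return default_temporal_matrix(9), chain_precision(9, 0.3)
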