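import numpy as np
import pandas as pd
import pytest

from maldipanel.features import FeatureMatrix
from maldipanel.io import SampleManifest, SpotPeakList
from maldipanel.reference import PeptideParams


@pytest.fixture
def single_peptide_config_kwargs():
    """Noise-free single-peptide study: exact-limit checks."""
    return dict(
        n_case=2,
        n_control=2,
        n_pool_replicates=0,
        peptide_params=[
            PeptideParams(
                peptide_id=1, mz=1000.0,
                case_mean=500.0, case_sd=250.0, case_freq=1.0,
                control_mean=500.0, control_sd=250.0, control_freq=1.0,
            )
        ],
        n_background=0,
        noise_cv=0.0,
        outlier_rate=0.0,
        mz_jitter_sd=0.0,
        dropout_midpoint=50.0,  # no detection loss at any dilution
        seed=7,
    )


def make_matrix(values: pd.DataFrame, groups: pd.Series) -> FeatureMatrix:
    """FeatureMatrix straight from an amplitude table (NaN = not detected)."""
    info = pd.DataFrame(
        {"consensus_mz": 0.0, "mz_sd": 0.0, "n_members": values.notna().sum()},
        index=values.columns,
    )
    info.index.name = "feature_id"
    return FeatureMatrix(values, info, groups)


def spot(spot_id, mz, intensity):
    return SpotPeakList(spot_id, np.asarray(mz, float), np.asarray(intensity, float))


def manifest_for(rows):
    return SampleManifest(pd.DataFrame(rows))
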