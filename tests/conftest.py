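import numpy as np
import pandas as pd
import pytest

from radplan.quantify import CountingStandard
from radplan.synth import (
    DEFAULT_MONKEY,
    gen_blood_curve,
    gen_gamma_counts,
    gen_organ_curves,
    gen_planar_study,
)

CAL_RATIO = 0.001


@pytest.fixture(scope="session")
def monkey_spec():
    return DEFAULT_MONKEY


@pytest.fixture(scope="session")
def counting_standard():
    return CountingStandard(
        counts=1.0e5, volume_counted=1.0, dilution_factor=100.0, administered_volume=2.0
    )


@pytest.fixture(scope="session")
def monkey_curves(monkey_spec):
    """Noise-free organ/whole-body %ID curves plus analytic truth."""
    return gen_organ_curves(monkey_spec)


@pytest.fixture(scope="session")
def planar_frame(monkey_curves):
    """Noise-free two-view ROI table plus truth."""
    curves, _ = monkey_curves
    return gen_planar_study(curves, CAL_RATIO)


@pytest.fixture()
def synthetic_study_dir(tmp_path, monkey_spec, monkey_curves, planar_frame, counting_standard):
    """A full noiseless synthetic monkey study on disk."""
    rois, _ = planar_frame
    blood, blood_truth = gen_blood_curve(monkey_spec)
    rois.to_csv(tmp_path / "planar_rois.csv", index=False)
    gen_gamma_counts(blood, counting_standard).to_csv(
        tmp_path / "gamma_counts.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "subject_id": blood.subject_id,
                "counts_cpm": counting_standard.counts,
                "volume_ml": counting_standard.volume_counted,
                "dilution_factor": counting_standard.dilution_factor,
                "administered_volume_ml": counting_standard.administered_volume,
            }
        ]
    ).to_csv(tmp_path / "counting_standard.csv", index=False)
    return tmp_path
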