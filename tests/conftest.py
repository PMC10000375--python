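import numpy as np
import pytest

from retinopipe import synthetic as syn
from retinopipe.segmentation import VesselSegmentation


@pytest.fixture(scope="session")
def clean_dr_fundus():
    """A 224x224 DR image with known lesions and no corruption."""
    return syn.generate_fundus(
        syn.FundusSpec(
            class_label="DR", n_microaneurysms=5, n_hemorrhages=2, seed=11,
            noise_density=0.0, blur_sigma=0.0, illumination_strength=0.0,
        )
    )


@pytest.fixture(scope="session")
def clean_normal_fundus():
    return syn.generate_fundus(
        syn.FundusSpec(seed=5, noise_density=0.0, blur_sigma=0.0, illumination_strength=0.0)
    )


def ground_truth_segmentation(lf: syn.LabeledFundus) -> VesselSegmentation:
    """Wrap generator masks so feature tests are independent of OPTICS."""
    return VesselSegmentation(
        vessel_mask=lf.vessel_mask,
        cluster_labels=np.empty(0, dtype=int),
        disc_mask=lf.disc_mask,
    )


@pytest.fixture
def gt_segmentation():
    return ground_truth_segmentation
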