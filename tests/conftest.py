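"""Shared fixtures: phantom subjects and derived pipeline stages.

Everything is generated programmatically from fixed seeds; session scope
keeps the expensive stages (vessel filtering of a full MRA volume) to a
single computation per run.
"""

import numpy as np
import pytest

from autoidif import phantom as ph
from autoidif import vessel_filter as vf
from autoidif.artery_segmentation import segment_arteries
from autoidif.core_io import Volume3D

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_config():
    return ph.PhantomConfig()


@pytest.fixture(scope="session")
def default_subject(default_config):
    """One phantom subject under the default study conditions."""
    mra, series, blood, truth = ph.generate_subject(default_config, DEFAULT_SEED)
    return {"mra": mra, "series": series, "blood": blood, "truth": truth,
            "config": default_config}


@pytest.fixture(scope="session")
def enhanced_mra(default_subject):
    """Multiscale-prolateness-enhanced MRA of the default subject."""
    mra = default_subject["mra"]
    scales = vf.default_scales(mra.spacing)
    pmap = vf.multiscale_prolateness(mra, scales)
    return vf.enhance(mra, pmap), pmap


@pytest.fixture(scope="session")
def segmented_subject(default_subject, enhanced_mra):
    """Default subject taken through segmentation."""
    enhanced, _ = enhanced_mra
    pet_ref = default_subject["series"].max_over_time()
    mask = segment_arteries(enhanced, pet_ref)
    return {**default_subject, "enhanced": enhanced, "pet_ref": pet_ref, "mask": mask}


@pytest.fixture(scope="session")
def clean_static_subject():
    """Noise-free, motion-free, catheter-free phantom (exact forward model)."""
    cfg = ph.PhantomConfig(pet_noise_scale=0.0, mra_noise_sigma=0.0,
                           mra_bias_amplitude=0.0, catheter_activity=0.0,
                           motion_x=(0.0, 0.0, 0.0), motion_y=(0.0, 0.0, 0.0))
    mra, series, blood, truth = ph.generate_subject(cfg, 11)
    return {"mra": mra, "series": series, "blood": blood, "truth": truth,
            "config": cfg}


@pytest.fixture
def rng():
    return np.random.default_rng(DEFAULT_SEED)


def truth_pv_map(subject) -> Volume3D:
    """Ground-truth fractional arterial occupancy (all arteries) on the PET grid."""
    cfg = subject["config"]
    return Volume3D(sum(subject["truth"].pet_artery_frac), cfg.pet_spacing,
                    cfg.pet_origin)
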