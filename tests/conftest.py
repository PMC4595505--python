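import numpy as np
import pytest

import falffkit as fk
from falffkit.preprocess import (BandSpec, MotionTrace, bandpass_filter,
                                 detrend_linear, discard_initial_volumes,
                                 smooth_gaussian)


@pytest.fixture(scope="session")
def design():
    """Default study-condition design at 120 volumes (desk-scale time axis)."""
    return fk.CohortDesign(n_volumes=120)


@pytest.fixture(scope="session")
def masks(design):
    brain, rois = fk.build_phantom_masks(design)
    return brain, rois


@pytest.fixture(scope="session")
def subject(design):
    return fk.simulate_subject_bold(design, "SUC", 42)


@pytest.fixture(scope="session")
def preprocessed(subject, masks):
    brain, _ = masks
    pre = discard_initial_volumes(subject.bold, 10)
    pre = smooth_gaussian(pre, 4.0)
    return detrend_linear(pre, brain)


@pytest.fixture(scope="session")
def cluster_null(masks):
    brain, _ = masks
    return fk.monte_carlo_cluster_null(brain, fwhm_mm=4.0, voxel_p_threshold=0.05,
                                       n_iterations=1000, seed=11)


def falff_branch(series, brain):
    """The amplitude-branch preprocessing used throughout the tests."""
    pre = detrend_linear(smooth_gaussian(discard_initial_volumes(series, 10), 4.0), brain)
    return fk.normalize_global_mean(fk.amplitude_map(pre, brain))


def fc_branch(rec, brain, rois, include_global=True):
    """The connectivity-branch preprocessing: discard, detrend, band-pass, nuisance."""
    from falffkit import connectivity as fc

    pre = bandpass_filter(
        detrend_linear(discard_initial_volumes(rec.bold, 10), brain), BandSpec())
    mot = MotionTrace(rec.motion.translations[10:], rec.motion.rotations[10:])
    nuis = fc.build_nuisance(mot, pre, rois["csf"], rois["wm"], brain, include_global)
    pre = fc.regress_nuisance_series(pre, nuis)
    return fc.fc_zmap(pre, fc.seed_timecourse(pre, rois["ba17"]), brain)


@pytest.fixture(scope="session")
def small_design():
    """Tiny single-region design for fast repeated simulation."""
    region = fk.RegionEffect(
        "blob", np.mgrid[4:7, 4:7, 4:7].reshape(3, -1).T,
        inband_gain={"A": 2.0, "B": 1.0})
    return fk.CohortDesign(grid_shape=(12, 12, 12), n_volumes=64,
                           group_sizes={"A": 2, "B": 2},
                           region_specs=[region], seed_region="blob")
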