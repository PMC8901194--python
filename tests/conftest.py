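"""Shared fixtures: small, fast synthetic recordings for unit tests and a
session-scoped full-study analysis for the heavier end-to-end checks."""

from dataclasses import replace

import numpy as np
import pytest

from nirscr import (SimConfig, SubjectProfile, build_default_montage,
                    default_profiles, simulate_recording)


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


@pytest.fixture()
def cfg():
    return SimConfig()


@pytest.fixture()
def small_cfg():
    """Reduced protocol: 8 trials, shorter baselines (~370 s, ~3300 samples)."""
    return SimConfig(n_trials=8, baseline_start_s=60.0, baseline_end_s=30.0)


@pytest.fixture()
def strong_profile():
    return SubjectProfile(1, "strong", amplitude_uM=0.40,
                          mw_amplitude=1.0, raw_mean_intensity_v=0.30)


@pytest.fixture()
def small_recording(small_cfg, strong_profile):
    rec, truth = simulate_recording(strong_profile, small_cfg, 1, 1)
    return rec, truth


@pytest.fixture(scope="session")
def study_analysis():
    """Full 15-subject x 2-session x 2-run study, preprocessed and fitted.

    Session-scoped because it backs several end-to-end assertions; the BCI
    stage is exercised separately on a canonical subject.
    """
    import warnings

    from nirscr import analyze_study, simulate_study

    cfg = SimConfig(seed=0)
    study = simulate_study(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        analysis = analyze_study(study, run_bci=False)
    return cfg, study, analysis
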