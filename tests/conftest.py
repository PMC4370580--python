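"""Shared fixtures: one default atlas and a few pre-simulated events.

Everything is generated programmatically; session scope keeps the slower
movie simulations to one run each.
"""

import numpy as np
import pytest

from vsdwave import build_region_atlas, make_event_spec, simulate_event
from vsdwave.events import AnalysisConfig, characterize_event
from vsdwave.preprocess import PreprocessConfig, run_chain
from vsdwave.wavefront import (clean_onset_map, compute_threshold_map,
                               detect_onsets)


@pytest.fixture(scope="session")
def atlas():
    return build_region_atlas()


@pytest.fixture(scope="session")
def atlas_binned(atlas):
    return atlas.rebin(2)


def _simulated(atlas, etype, **kw):
    spec = make_event_spec(etype, atlas, **kw)
    movie, truth = simulate_event(spec, atlas)
    return movie, truth, spec


@pytest.fixture(scope="session")
def event_3a(atlas):
    return _simulated(atlas, "3a")


@pytest.fixture(scope="session")
def event_3b(atlas):
    return _simulated(atlas, "3b", reverb_latency_s=0.6)


@pytest.fixture(scope="session")
def event_1(atlas):
    return _simulated(atlas, "1")


@pytest.fixture(scope="session")
def event_2(atlas):
    return _simulated(atlas, "2")


def detect_clean(movie, config=None):
    """Default detection chain on one movie (validated, cleaned)."""
    cfg = config or PreprocessConfig()
    filtered, dff = run_chain(movie, cfg)
    thr_f = compute_threshold_map(filtered, cfg.baseline_window_s)
    thr_d = compute_threshold_map(dff, cfg.baseline_window_s)
    onsets = detect_onsets(filtered, thr_f, validation_movie=dff,
                           validation_threshold_map=thr_d)
    return clean_onset_map(onsets)


@pytest.fixture(scope="session")
def onsets_3a(event_3a):
    movie, _truth, _spec = event_3a
    return detect_clean(movie)


@pytest.fixture(scope="session")
def record_3b(event_3b, atlas):
    movie, _truth, _spec = event_3b
    return characterize_event(movie, atlas, AnalysisConfig())


def binned_truth(truth):
    """Ground-truth onsets block-reduced (min) onto the 2x2-binned grid."""
    gt = truth.onset.onset_s
    hh, ww = gt.shape[0] // 2, gt.shape[1] // 2
    blocks = gt[: hh * 2, : ww * 2].reshape(hh, 2, ww, 2)
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.nanmin(blocks, axis=(1, 3))
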