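"""Shared fixtures: small phantom scenes reused across the suite.

Scene builds are the expensive part of the suite, so anything used by more
than one test module is session-scoped.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from bbflow import phantom, pipeline


@pytest.fixture(scope="session")
def tube_spec():
    return phantom.GeometrySpec(kind="straight_tube", inner_diameter=4.0, tube_length=60.0)


@pytest.fixture(scope="session")
def tube_geometry(tube_spec):
    return phantom.build_geometry(tube_spec)


@pytest.fixture(scope="session")
def tube_scene(tube_spec):
    """Misaligned, noisy straight-tube scene at the 4.7 ml/s pump setting."""
    return phantom.make_scene(
        tube_spec,
        phantom.FlowSpec(mean_flow_rate=4.7),
        spacing=0.7,
        n_phases=8,
        noise_sigma=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tube_scene_clean(tube_spec):
    """Noiseless, misaligned tube scene (registration / segmentation truth)."""
    return phantom.make_scene(
        tube_spec,
        phantom.FlowSpec(mean_flow_rate=4.7),
        spacing=0.7,
        n_phases=4,
        noise_sigma=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def sidewall_spec():
    """Sidewall-aneurysm geometry with the patient-specific ICA sac dimensions."""
    return phantom.GeometrySpec(
        kind="sidewall_aneurysm",
        inner_diameter=4.0,
        tube_length=50.0,
        sac_dims=(14.1, 7.7, 13.4),
    )


@pytest.fixture(scope="session")
def sidewall_geometry(sidewall_spec):
    return phantom.build_geometry(sidewall_spec)


@pytest.fixture(scope="session")
def sidewall_clean_quant(sidewall_spec):
    """Noiseless misaligned sidewall scene pushed through the full
    measurement chain; exercises segmentation + ICP + VOI transfer truth."""
    scene = phantom.make_scene(
        sidewall_spec,
        phantom.FlowSpec(mean_flow_rate=4.5),
        spacing=0.7,
        n_phases=2,
        noise_sigma=0.0,
        seed=21,
    )
    return pipeline.quantify_scene(scene)


@pytest.fixture(scope="session")
def ica_treatment_run(tmp_path_factory):
    """Untreated vs strong flow diverter (k = 0.05) on the ICA-like model,
    through the full pipeline.  Used for direction/magnitude checks."""
    out = tmp_path_factory.mktemp("ica_run")
    ica = pipeline.default_models()[0]
    cfg = pipeline.RunConfig(
        seed=7,
        models=[ica],
        devices=[pipeline.DeviceSpec("FD_strong", "ICA", 0.05)],
        spacing=0.7,
        n_phases=8,
        output_dir=str(out),
    )
    return pipeline.run_experiment(cfg)
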