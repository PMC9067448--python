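from dataclasses import replace

import pytest

import arterymap as am
from arterymap.synthetic import (
    default_phantom_spec,
    default_vessel_paths,
    generate_phantom,
)

# Small-head study phantom used across tests: 60 mm cube at 0.5 mm.
PHANTOM_SHAPE = (120, 120, 120)
PHANTOM_CENTER = (30.0, 30.0, 30.0)
PHANTOM_AXES = (24.0, 26.0, 28.0)


def small_phantom_spec(seed=0, vessels=None, noise_sigma=None):
    spec = default_phantom_spec(seed=seed, shape=PHANTOM_SHAPE)
    spec = replace(
        spec,
        head_center_mm=PHANTOM_CENTER,
        head_semiaxes_mm=PHANTOM_AXES,
        vessels=(
            vessels
            if vessels is not None
            else default_vessel_paths(PHANTOM_CENTER, PHANTOM_AXES)
        ),
    )
    if noise_sigma is not None:
        spec = replace(spec, noise_sigma=noise_sigma)
    return spec


def run_segmentation_chain(vol, cfg=None):
    """vesselness -> threshold -> band -> separation -> skeleton."""
    from arterymap.pipeline import PipelineConfig

    cfg = cfg or PipelineConfig()
    vmap = am.multiscale_vesselness(vol, cfg.scales_mm, cfg.tau, cfg.polarity)
    vmask = am.threshold_segment(vmap, cfg.threshold)
    band = am.subcutaneous_band_mask(vol, cfg.band_depth_mm, cfg.skin_offset_mm)
    mask = am.separate_superficial(vmask, band, cfg.min_component_voxels)
    lines = am.skeletonize_centerlines(mask, min_branch_mm=cfg.min_branch_mm)
    return vmap, band, mask, lines


@pytest.fixture(scope="session")
def table_records():
    return am.load_deviation_table()


@pytest.fixture(scope="session")
def noisefree_tube_run():
    """Noise-free single-tube head phantom plus its full segmentation chain."""
    vessels = [
        v
        for v in default_vessel_paths(PHANTOM_CENTER, PHANTOM_AXES)
        if str(v.label) == "ST-left"
    ]
    spec = small_phantom_spec(seed=0, vessels=vessels, noise_sigma=0.0)
    vol, truth = generate_phantom(spec)
    vmap, band, mask, lines = run_segmentation_chain(vol)
    return dict(
        spec=spec, vol=vol, truth=truth, vmap=vmap, band=band, mask=mask,
        lines=lines,
    )


@pytest.fixture(scope="session")
def noisy_full_run():
    """Default 18-artery phantom at 5% noise plus its segmentation chain."""
    spec = small_phantom_spec(seed=1)
    vol, truth = generate_phantom(spec)
    vmap, band, mask, lines = run_segmentation_chain(vol)
    return dict(
        spec=spec, vol=vol, truth=truth, vmap=vmap, band=band, mask=mask,
        lines=lines,
    )
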