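import numpy as np
import pytest

import limbtrack as lt


@pytest.fixture(scope="session")
def phantom_bundle():
    """Default phantom: volume, generative labels, joint origins."""
    vol, labels, joints = lt.make_limb_phantom()
    return vol, labels, joints


@pytest.fixture(scope="session")
def seg_bundle(phantom_bundle):
    """Segmentation of the default phantom plus PCA frames."""
    vol, _, _ = phantom_bundle
    seg = lt.segment_bones(vol)
    frames = [lt.bone_frame(seg, b, end_hint=+1) for b in (1, 2)]
    return seg, frames


@pytest.fixture(scope="session")
def fusion_cfg():
    # support must cover the articulation displacements at phantom scale
    return lt.FusionConfig(S=18, sigma_f=5.0, k_f=29)


@pytest.fixture(scope="session")
def fusion_maps(seg_bundle, fusion_cfg):
    seg, _ = seg_bundle
    return lt.fusion_weights(seg, [1, 2], fusion_cfg)


@pytest.fixture(scope="session")
def landmark_sets(seg_bundle):
    seg, frames = seg_bundle
    sel = lt.SelectionConfig(K=20, lam=1.5)
    return [
        lt.select_landmarks(lt.candidate_bone_voxels(seg, b), f, sel, kind="bounding")
        for b, f in zip((1, 2), frames)
    ]


def make_model(seg, frames, etas, fusion_cfg, maps):
    return lt.build_articulation_model(seg, frames, etas, fusion_cfg, weights=maps)


@pytest.fixture(scope="session")
def zero_model(seg_bundle, fusion_cfg, fusion_maps):
    seg, frames = seg_bundle
    return make_model(seg, frames, [0.0, 0.0], fusion_cfg, fusion_maps)


@pytest.fixture(scope="session")
def study_geometry():
    """Acquisition used for phantom pose studies: source/detector
    distances follow the study protocol; the detector is unbinned so the
    phantom subtends a pixel extent comparable to the original images."""
    return lt.ConeBeamGeometry(sod=6550.0, sdd=10000.0, det_rows=512,
                               det_cols=512, det_pitch=1.0, binning=1)
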