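import numpy as np
import pytest

from octavg import ScaleModel, SyntheticScene


@pytest.fixture(scope="session")
def scale():
    return ScaleModel()


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, misalignment-free scene at ROI-ish size."""
    return SyntheticScene(
        image_size_px=(80, 80),
        icd_jitter_frac=0.0,
        tortuosity_amp_um=0.0,
        anastomosis_rate=0.0,
        speckle_sigma=0.0,
        additive_sigma=0.0,
        motion_line_prob=0.0,
        shift_range_px=0.0,
        rot_range_deg=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-noise scene at a small field for fast simulation."""
    return SyntheticScene(image_size_px=(80, 80), seed=11)


def brute_force_endpoint_branch(skel: np.ndarray):
    """Independent 3x3 neighbour-count pass: endpoint pixels (<=1
    neighbour) and branch pixels (>=3 neighbours) of a binary skeleton."""
    skel = np.asarray(skel, bool)
    h, w = skel.shape
    endpoints, branches = set(), set()
    for r in range(h):
        for c in range(w):
            if not skel[r, c]:
                continue
            n = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                        n += 1
            if n <= 1:
                endpoints.add((r, c))
            if n >= 3:
                branches.add((r, c))
    return endpoints, branches
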