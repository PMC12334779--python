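import numpy as np
import pytest

import focalindex as fx


@pytest.fixture(scope="session")
def focal_phantom():
    """Fully separated phantom (phi=1), ~1e4 voxels in the smallest ROI."""
    cfg = fx.default_config(phi=1.0, seed=42, target_roi_voxels=10_000)
    volume, mask, truth = fx.generate_phantom(cfg)
    return cfg, volume, mask, truth


@pytest.fixture(scope="session")
def homogeneous_phantom():
    """Homogeneous phantom (phi=0): every region draws from one law."""
    cfg = fx.default_config(phi=0.0, seed=7, target_roi_voxels=10_000)
    volume, mask, truth = fx.generate_phantom(cfg)
    return cfg, volume, mask, truth


@pytest.fixture()
def cuboid_lung():
    """A uniform cuboid 'lung' spanning 18 slices; all nine ROI counts equal."""
    shape = (20, 62, 40)
    voxels = np.full(shape, -500.0)
    mask = np.zeros(shape, dtype=bool)
    mask[1:19, 10:52, 5:35] = True  # 18 slices, 42 AP rows, 30 LR cols
    return (
        fx.CTVolume(voxels=voxels, spacing=(1.5, 1.0, 1.0), source_id="cuboid"),
        fx.LungMask(labels=mask),
    )


def make_volume(voxels, spacing=(1.5, 1.0, 1.0), source_id="test"):
    return fx.CTVolume(voxels=np.asarray(voxels, dtype=float), spacing=spacing, source_id=source_id)
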