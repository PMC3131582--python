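import numpy as np
import pytest
from hypothesis import settings

import chipcyto as cc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    return cc.ChipGeometry()


@pytest.fixture(scope="session")
def flow():
    return cc.FlowConfig()


@pytest.fixture(scope="session")
def optics():
    return cc.OpticsModel()


@pytest.fixture(scope="session")
def recog():
    return cc.RecognitionConfig()


@pytest.fixture(scope="session")
def occupancy_run(geometry, flow, optics):
    """10^4 truth-only frames at the reference density (λ = 0.125)."""
    pop = cc.ParticlePopulation(label="3um", diameter_mean=3.0)
    return cc.simulate_stream(
        [pop], [1.0], flow, geometry, optics,
        density=1e6, duration=50.0, seed=20_240_125, render=False,
    )


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Independent BFS flood-fill oracle: list of sets of (row, col)."""
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    rows, cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy, dx in offsets:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < rows and 0 <= nx < cols:
                            if mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                comps.append(comp)
    return comps


def disc_mask(radius_px: float, pad: int = 3) -> np.ndarray:
    n = int(np.ceil(2 * radius_px)) + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    cy = cx = n // 2
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2


def region_from_mask(mask: np.ndarray) -> cc.recognition.BlobRegion:
    rr, ccc = np.nonzero(mask)
    return cc.recognition.BlobRegion(
        coords=np.column_stack((rr, ccc)),
        bbox=(int(rr.min()), int(ccc.min()), int(rr.max()) + 1, int(ccc.max()) + 1),
    )
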