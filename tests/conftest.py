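import math

import numpy as np
import pytest

from bcdburst import EmbryoSpec, IntronDot, NucleusRecord, generate_embryo
from bcdburst.pipeline import process_embryo


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-canvas embryo used by most unit tests (~60 nuclei)."""
    return EmbryoSpec(width=1024, height=256, seed=11)


@pytest.fixture(scope="session")
def small_embryo(small_spec):
    return generate_embryo(small_spec)


@pytest.fixture(scope="session")
def processed_small(small_embryo):
    image, truth = small_embryo
    return process_embryo(image, thresholds=(32, 4), truth=truth)


def make_disc_nucleus(nid, center, radius_px, shape, pixel_size=0.16):
    """Hand-built circular NucleusRecord for synthetic unit scenarios."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    m = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px ** 2
    rows, cols = np.nonzero(m)
    return NucleusRecord(
        id=nid, pixels=(rows, cols),
        centroid=(float(rows.mean()), float(cols.mean())),
        diameter_um=2 * math.sqrt(len(rows) / math.pi) * pixel_size,
        pixel_size=pixel_size)


def make_dot(center, nucleus_id=None, size=4, intensity=40.0):
    r, c = int(center[0]), int(center[1])
    rows = np.array([r, r, r + 1, r + 1])[:size]
    cols = np.array([c, c + 1, c, c + 1])[:size]
    return IntronDot(pixels=(rows, cols), size=size,
                     centroid=(float(rows.mean()), float(cols.mean())),
                     raw_intensity=float(intensity) * size,
                     nucleus_id=nucleus_id)
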