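"""Reading and writing of image and tabular pipeline artifacts.

Images travel as multi-page TIFF, one page per channel, in a fixed
configured order (TIFF pages are unlabeled). Tables are plain CSV with
documented headers; floats are written at 6 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .exceptions import PipelineError
from .synth import CHANNEL_ORDER, EmbryoImage

FLOAT_FORMAT = "%.6g"


def read_embryo_tiff(path, channel_order=("envelope", "bcd", "intron"),
                     pixel_size: float = 0.16) -> EmbryoImage:
    """Read a multi-page TIFF into an EmbryoImage.

    ``channel_order`` names the pages in file order; a file with fewer
    pages than named channels raises a PipelineError naming the first
    missing channel.
    """
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < len(channel_order):
        missing = channel_order[stack.shape[0]]
        raise PipelineError(
            f"input TIFF {path} has {stack.shape[0]} page(s); channel "
            f"{missing!r} is missing (expected order {list(channel_order)})")
    unknown = set(channel_order) - set(CHANNEL_ORDER)
    if unknown:
        raise PipelineError(f"unknown channel name(s) {sorted(unknown)}")
    channels = {name: np.asarray(stack[i], dtype=np.uint8)
                for i, name in enumerate(channel_order)}
    return EmbryoImage(channels=channels, pixel_size=pixel_size)


def write_table(df, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
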