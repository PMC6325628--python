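"""TIFF input/output for volumes, channel stacks and masks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .chip import ChannelStack


def write_volume(path, vol: np.ndarray) -> None:
    """Multi-page TIFF, one page per z-plane (float32)."""
    tifffile.imwrite(str(path), np.asarray(vol, dtype=np.float32))


def read_volume(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_mask(path, mask: np.ndarray) -> None:
    """Binary mask as 8-bit TIFF (255 = foreground)."""
    tifffile.imwrite(str(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def write_stack(path, stack: ChannelStack) -> None:
    """OME-TIFF with channel names in metadata; axes CZYX."""
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(
        str(path), data, ome=True,
        metadata={"axes": "CZYX", "Channel": {"Name": names}},
    )


def read_stack(path, channel_names: list[str] | None = None) -> ChannelStack:
    """Read an OME-TIFF stack; channel names from metadata unless given."""
    path = str(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        if channel_names is None:
            import re

            ome = tif.ome_metadata or ""
            channel_names = re.findall(r'Channel[^>]*Name="([^"]+)"', ome)
    if data.ndim == 3:
        data = data[None]
    if not channel_names or len(channel_names) != data.shape[0]:
        raise ValueError(
            f"cannot map {data.shape[0]} channels in {Path(path).name}; "
            "pass channel_names explicitly"
        )
    return ChannelStack({n: data[i] for i, n in enumerate(channel_names)})
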