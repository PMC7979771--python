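"""Frame-stack and table IO helpers shared by the CLI.

Frame stacks are stored either as a single ``.npy`` array (n, H, W) or as a
directory of PNG files in lexicographic frame order; the format is chosen by
the path's extension.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def write_frames(stack: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, stack)
        return
    path.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(stack):
        iio.imwrite(path / f"frame_{k:06d}.png", frame)


def read_frames(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        return np.stack([iio.imread(f) for f in files])
    raise ValueError(f"unsupported frame source: {path}")
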