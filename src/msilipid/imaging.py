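"""Slicing per-pixel values into 2-D images and rendering them to files.

Orientation contract: increasing y goes down the image, increasing x goes
right, i.e. grid[y-1, x-1] holds the value of pixel (x, y).  Pixels with no
acquired spectrum carry NaN, never 0 — zero is a valid intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.cm as cm
import matplotlib.colors as mcolors
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["IonImage", "slice_image", "render", "overlay_rgb"]


@dataclass
class IonImage:
    """A 2-D value grid for one feature, score component or label map."""

    grid: np.ndarray  # n_y x n_x, NaN background
    mz: float | int | None
    value_kind: str = "intensity"  # "intensity" | "score" | "label"

    def __post_init__(self) -> None:
        if self.value_kind not in ("intensity", "score", "label"):
            raise ValueError(f"invalid value_kind {self.value_kind!r}")


def slice_image(
    values: np.ndarray,
    grid: tuple[int, int],
    pixel_index: list[tuple[int, int]],
    mz: float | int | None = None,
    value_kind: str = "intensity",
) -> IonImage:
    """Place one value per acquired pixel onto the full grid.

    *values* is aligned to *pixel_index*; missing pixels become NaN.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(pixel_index):
        raise ValueError(
            f"{len(values)} values for {len(pixel_index)} pixels"
        )
    n_x, n_y = grid
    img = np.full((n_y, n_x), np.nan)
    for v, (x, y) in zip(values, pixel_index):
        if not (1 <= x <= n_x and 1 <= y <= n_y):
            raise ValueError(f"pixel {(x, y)} outside grid {grid}")
        img[y - 1, x - 1] = v
    return IonImage(grid=img, mz=mz, value_kind=value_kind)


def flatten_image(image: IonImage, pixel_index: list[tuple[int, int]]) -> np.ndarray:
    """Inverse of slice_image over the acquired pixels."""
    return np.array([image.grid[y - 1, x - 1] for x, y in pixel_index])


def render(
    image: IonImage,
    path: str | Path,
    colormap: str = "viridis",
    scale: str = "linear",
) -> Path:
    """Write the image as a PNG raster; deterministic for fixed inputs.

    Label images use a categorical palette; intensity/score images use the
    given colormap with optional arcsinh compression.  NaN background is
    rendered black.
    """
    if scale not in ("linear", "arcsinh"):
        raise ValueError(f"unknown scale {scale!r}")
    path = Path(path)
    grid = image.grid
    if image.value_kind == "label":
        cmap = plt.get_cmap("tab10")
        labels = np.unique(grid[~np.isnan(grid)]).astype(int)
        rgba = np.zeros(grid.shape + (4,))
        for i, lab in enumerate(labels):
            rgba[grid == lab] = cmap(i % 10)
        rgba[np.isnan(grid)] = (0, 0, 0, 1)
        plt.imsave(path, rgba)
        return path
    values = np.arcsinh(grid) if scale == "arcsinh" else grid
    finite = values[np.isfinite(values)]
    vmin = float(finite.min()) if len(finite) else 0.0
    vmax = float(finite.max()) if len(finite) else 1.0
    if vmax == vmin:
        vmax = vmin + 1.0
    cmap = plt.get_cmap(colormap).copy()
    cmap.set_bad(color="black")
    norm = mcolors.Normalize(vmin=vmin, vmax=vmax)
    rgba = cmap(norm(np.ma.masked_invalid(values)))
    plt.imsave(path, rgba)
    return path


def overlay_rgb(
    images: list[IonImage],
    path: str | Path,
) -> Path:
    """Composite up to three intensity images as R, G, B channels."""
    if not 1 <= len(images) <= 3:
        raise ValueError("overlay takes 1-3 images")
    shape = images[0].grid.shape
    rgb = np.zeros(shape + (3,))
    for chan, img in enumerate(images):
        if img.grid.shape != shape:
            raise ValueError("overlay images must share a grid")
        g = np.nan_to_num(img.grid, nan=0.0)
        top = g.max()
        rgb[:, :, chan] = g / top if top > 0 else 0.0
    path = Path(path)
    plt.imsave(path, rgb)
    return path
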