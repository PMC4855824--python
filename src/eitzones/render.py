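"""Classified-region maps in the conventional display: overinflated regions
white, tidally recruited/derecruited red, recruited blue, lung outline
yellow on a black background, with per-category percentages printed beneath
the map.

Rendering is a pure function of (step result, palette, scale): identical
inputs produce byte-identical PNG files.  Upscaling is nearest-neighbour so
single-pixel findings remain auditable.  Where a pixel belongs to several
categories, display precedence is overinflated > cyclic > recruited >
lung background — overinflation wins because it is the safety-critical
finding; pixel *counts* are never affected by this, it is purely a display
decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy.ndimage import binary_erosion

from .errors import ValidationError
from .trial import StepResult

RGB = tuple[int, int, int]


@dataclass(frozen=True)
class Palette:
    """Display colors; the category colors must be pairwise distinct."""

    overinflated: RGB = (255, 255, 255)  # white
    recruited: RGB = (0, 0, 255)         # blue
    cyclic: RGB = (255, 0, 0)            # red
    outline: RGB = (255, 255, 0)         # yellow lung outline
    lung: RGB = (70, 70, 70)             # unclassified lung interior
    background: RGB = (0, 0, 0)
    text: RGB = (180, 180, 180)

    def __post_init__(self) -> None:
        colors = [self.overinflated, self.recruited, self.cyclic,
                  self.outline, self.background]
        if len(set(colors)) != len(colors):
            raise ValidationError("palette colors must be distinct")


def render_map(
    step: StepResult,
    palette: Palette | None = None,
    scale: int = 8,
    show_percentages: bool = True,
    outline: bool = True,
) -> Image.Image:
    """Render one analyzed PEEP step as a raster map.

    The union of the end-expiratory and tidal lung regions is outlined
    (outline drawn only over unclassified pixels so category pixels stay
    auditable).  Empty masks render as a plain background with 0.0 % labels.
    """
    if scale < 1:
        raise ValidationError("scale must be at least 1")
    pal = palette or Palette()

    masks = step.masks
    if masks is not None:
        shape = masks.lung_ee.shape
        lung_ee, lung_tidal = masks.lung_ee, masks.lung_tidal
        over, cyc = masks.overinflated, masks.cyclic
        rec = masks.recruited if masks.recruited is not None else np.zeros(shape, bool)
    else:
        shape = (32, 32)
        lung_ee = lung_tidal = over = cyc = rec = np.zeros(shape, bool)

    rgb = np.empty((*shape, 3), dtype=np.uint8)
    rgb[:] = pal.background
    union = lung_ee | lung_tidal
    rgb[union] = pal.lung
    # ascending display precedence
    rgb[rec] = pal.recruited
    rgb[cyc] = pal.cyclic
    rgb[over] = pal.overinflated
    if outline:
        border = union & ~binary_erosion(union)
        unclassified = border & ~(rec | cyc | over)
        rgb[unclassified] = pal.outline

    rgb = np.repeat(np.repeat(rgb, scale, axis=0), scale, axis=1)
    img = Image.fromarray(rgb, mode="RGB")

    if show_percentages:
        pct = step.percentages
        label = "  ".join(
            f"{tag} {pct.get(key, 0.0):.1f}%"
            for tag, key in (("OD", "overinflated"), ("TR", "cyclic"), ("REC", "recruited"))
        )
        font_size = max(10, 2 * scale)
        strip = font_size + 8
        canvas = Image.new("RGB", (img.width, img.height + strip), pal.background)
        canvas.paste(img, (0, 0))
        draw = ImageDraw.Draw(canvas)
        font = ImageFont.load_default(size=font_size)
        draw.text((4, img.height + 3), label, fill=pal.text, font=font)
        img = canvas
    return img


def save_map(
    step: StepResult,
    path: str | Path,
    palette: Palette | None = None,
    scale: int = 8,
    **kwargs,
) -> Path:
    """Render and write a PNG map; returns the path written."""
    path = Path(path)
    render_map(step, palette=palette, scale=scale, **kwargs).save(path, format="PNG")
    return path
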