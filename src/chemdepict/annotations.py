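"""Non-structural annotations: identity / rest-group / condition labels
and curved or straight arrows, placed relative to the structure mask."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy import ndimage

from .vocab import (
    REAGENTS,
    REST_GROUP_VARIABLES,
    SOLVENTS,
    SUPERATOM_LABELS,
    available_font_files,
)

__all__ = [
    "LabelSpec",
    "ArrowSpec",
    "gen_identity_label",
    "gen_rest_group_label",
    "gen_reaction_condition_label",
    "structure_mask",
    "place_label",
    "place_arrow",
    "arrow_glyphs",
]

logger = logging.getLogger(__name__)

LABEL_KINDS = ("identity", "rest_group", "reaction_condition")
ARROW_KINDS = ("curved", "straight")
DASHES = ("-", "–")  # hyphen or en-dash
MAX_PLACEMENT_ATTEMPTS = 50


@dataclass(frozen=True)
class LabelSpec:
    kind: str
    text: str
    font_id: str
    font_size: int

    def __post_init__(self) -> None:
        if self.kind not in LABEL_KINDS:
            raise ValueError(f"unknown label kind {self.kind!r}")
        if not self.text:
            raise ValueError("label text must be non-empty")


@dataclass(frozen=True)
class ArrowSpec:
    kind: str
    glyph_id: str
    rotation: float
    scale: float
    position: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in ARROW_KINDS:
            raise ValueError(f"unknown arrow kind {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("arrow scale must be positive")


def _pick_font(rng: np.random.Generator) -> Tuple[str, int]:
    fonts = available_font_files()
    font_id = f"font_{int(rng.integers(0, max(len(fonts), 1))):02d}"
    size = int(rng.integers(10, 25))
    return font_id, size


def gen_identity_label(rng: np.random.Generator) -> LabelSpec:
    """Identity label: "1", "1a", "1-4" or "1a-d" style text."""
    font_id, size = _pick_font(rng)
    form = int(rng.integers(0, 4))
    n = int(rng.integers(1, 100))
    dash = DASHES[int(rng.integers(0, 2))]
    if form == 0:
        text = str(n)
    elif form == 1:
        text = f"{n}{chr(ord('a') + int(rng.integers(0, 26)))}"
    elif form == 2:
        text = f"{n}{dash}{int(rng.integers(1, 100))}"
    else:
        first = int(rng.integers(0, 25))
        second = int(rng.integers(first + 1, 26))
        text = f"{n}{chr(ord('a') + first)}{dash}{chr(ord('a') + second)}"
    return LabelSpec("identity", text, font_id, size)


def gen_rest_group_label(rng: np.random.Generator) -> LabelSpec:
    """Rest-group label: variable (optionally indexed) = superatom."""
    font_id, size = _pick_font(rng)
    var = REST_GROUP_VARIABLES[int(rng.integers(0, len(REST_GROUP_VARIABLES)))]
    if rng.random() < 0.5:
        var = f"{var}{int(rng.integers(1, 10))}"
    superatom = SUPERATOM_LABELS[int(rng.integers(0, len(SUPERATOM_LABELS)))]
    return LabelSpec("rest_group", f"{var} = {superatom}", font_id, size)


def gen_reaction_condition_label(rng: np.random.Generator) -> LabelSpec:
    """Condition label: reagent, solvent, duration — rendered on 1-3 lines."""
    font_id, size = _pick_font(rng)
    reagent = REAGENTS[int(rng.integers(0, len(REAGENTS)))]
    solvent = SOLVENTS[int(rng.integers(0, len(SOLVENTS)))]
    unit = "h" if rng.random() < 0.5 else "min"
    amount = int(rng.integers(1, 25 if unit == "h" else 121))
    fields = [reagent, solvent, f"{amount} {unit}"]
    n_lines = int(rng.integers(1, 4))
    if n_lines == 1:
        text = ", ".join(fields)
    elif n_lines == 2:
        text = f"{fields[0]}, {fields[1]},\n{fields[2]}"
    else:
        text = ",\n".join(fields)
    return LabelSpec("reaction_condition", text, font_id, size)


def structure_mask(image: Image.Image, threshold: int = 250, dilate: int = 2) -> np.ndarray:
    """Boolean mask of non-background pixels, dilated by ``dilate`` px."""
    arr = np.asarray(image.convert("RGB"))
    mask = (arr < threshold).any(axis=2)
    if dilate > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=dilate)
    return mask


def _load_font(spec: LabelSpec) -> ImageFont.ImageFont:
    fonts = available_font_files()
    if fonts:
        try:
            idx = int(spec.font_id.split("_")[-1]) % len(fonts)
            return ImageFont.truetype(fonts[idx], spec.font_size)
        except Exception:
            pass
    try:
        return ImageFont.load_default(size=spec.font_size)
    except TypeError:
        return ImageFont.load_default()


def place_label(
    image: Image.Image,
    spec: LabelSpec,
    mask: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = MAX_PLACEMENT_ATTEMPTS,
) -> Image.Image:
    """Draw a label in a free region; unchanged copy if no region found."""
    img = image.copy()
    draw = ImageDraw.Draw(img)
    font = _load_font(spec)
    bbox = draw.multiline_textbbox((0, 0), spec.text, font=font)
    tw, th = bbox[2] - bbox[0], bbox[3] - bbox[1]
    W, H = img.size
    if tw >= W or th >= H:
        logger.info("label %r too large for canvas, skipped", spec.text)
        return img
    for _ in range(max_attempts):
        x = int(rng.integers(0, W - tw))
        y = int(rng.integers(0, H - th))
        region = mask[y : y + th + 2, x : x + tw + 2]
        if not region.any():
            draw.multiline_text((x - bbox[0], y - bbox[1]), spec.text,
                                fill=(0, 0, 0), font=font)
            return img
    logger.info("no free region for label %r after %d attempts, skipped",
                spec.text, max_attempts)
    return img


# ---------------------------------------------------------------------------
# arrows

_GLYPH_SIZE = 128
_glyph_cache: Optional[Dict[str, Image.Image]] = None


def _head(draw: ImageDraw.ImageDraw, tip: Tuple[float, float], angle: float,
          size: float = 14.0) -> None:
    a1, a2 = angle + math.radians(150), angle - math.radians(150)
    pts = [
        tip,
        (tip[0] + size * math.cos(a1), tip[1] + size * math.sin(a1)),
        (tip[0] + size * math.cos(a2), tip[1] + size * math.sin(a2)),
    ]
    draw.polygon(pts, fill=(0, 0, 0, 255))


def arrow_glyphs() -> Dict[str, Image.Image]:
    """Procedurally drawn RGBA arrow glyphs, keyed by glyph id."""
    global _glyph_cache
    if _glyph_cache is not None:
        return _glyph_cache
    s = _GLYPH_SIZE
    glyphs: Dict[str, Image.Image] = {}

    def new():
        img = Image.new("RGBA", (s, s), (0, 0, 0, 0))
        return img, ImageDraw.Draw(img)

    img, d = new()
    d.line([(8, s // 2), (s - 16, s // 2)], fill=(0, 0, 0, 255), width=5)
    _head(d, (s - 8, s // 2), 0.0)
    glyphs["straight_plain"] = img

    img, d = new()
    for x in range(8, s - 20, 14):
        d.line([(x, s // 2), (x + 8, s // 2)], fill=(0, 0, 0, 255), width=5)
    _head(d, (s - 8, s // 2), 0.0)
    glyphs["straight_dashed"] = img

    img, d = new()  # equilibrium double arrow
    d.line([(10, s // 2 - 10), (s - 18, s // 2 - 10)], fill=(0, 0, 0, 255), width=4)
    _head(d, (s - 8, s // 2 - 10), 0.0, size=11)
    d.line([(18, s // 2 + 10), (s - 10, s // 2 + 10)], fill=(0, 0, 0, 255), width=4)
    _head(d, (8, s // 2 + 10), math.pi, size=11)
    glyphs["straight_double"] = img

    img, d = new()  # clockwise curved (mechanism) arrow
    d.arc([12, 12, s - 12, s - 12], start=300, end=180, fill=(0, 0, 0, 255), width=5)
    _head(d, (s // 2 + 22, s - 16), math.radians(-160))
    glyphs["curved_cw"] = img

    img, d = new()
    d.arc([12, 12, s - 12, s - 12], start=0, end=240, fill=(0, 0, 0, 255), width=5)
    _head(d, (s - 14, s // 2 + 18), math.radians(100))
    glyphs["curved_ccw"] = img

    img, d = new()  # double-headed curved arrow
    d.arc([12, 28, s - 12, s + 40], start=200, end=340, fill=(0, 0, 0, 255), width=5)
    _head(d, (16, s // 2 + 14), math.radians(120))
    _head(d, (s - 16, s // 2 + 14), math.radians(60))
    glyphs["curved_double"] = img

    _glyph_cache = glyphs
    return glyphs


def glyphs_of_kind(kind: str) -> Dict[str, Image.Image]:
    if kind not in ARROW_KINDS:
        raise ValueError(f"unknown arrow kind {kind!r}")
    return {k: v for k, v in arrow_glyphs().items() if k.startswith(kind)}


def place_arrow(
    image: Image.Image,
    kind: str,
    mask: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = MAX_PLACEMENT_ATTEMPTS,
    return_spec: bool = False,
):
    """Paste an arrow glyph: curved arrows must overlap the structure
    mask, straight arrows must avoid it.  Skips (with a log line) when no
    admissible position is found within ``max_attempts``.

    With ``return_spec=True`` returns ``(image, ArrowSpec or None)``.
    """
    glyphs = glyphs_of_kind(kind)
    names = sorted(glyphs)
    name = names[int(rng.integers(0, len(names)))]
    glyph = glyphs[name]

    W, H = image.size
    scale = float(rng.uniform(0.15, 0.35)) * min(W, H) / _GLYPH_SIZE
    size = max(int(_GLYPH_SIZE * scale), 8)
    rotation = float(rng.uniform(0, 360))
    g = glyph.resize((size, size), Image.BILINEAR).rotate(
        rotation, resample=Image.BILINEAR, expand=True
    )
    gw, gh = g.size
    if gw >= W or gh >= H:
        logger.info("arrow glyph too large for canvas, skipped")
        return (image.copy(), None) if return_spec else image.copy()

    want_overlap = kind == "curved"

    def paste(glyph_img, x, y):
        out = image.convert("RGBA")
        out.alpha_composite(glyph_img, (x, y))
        spec = ArrowSpec(kind, name, rotation, scale, (x, y))
        return (out.convert("RGB"), spec) if return_spec else out.convert("RGB")

    for shrink in range(4):  # progressively smaller glyph if space is tight
        gw, gh = g.size
        for _ in range(max_attempts):
            x = int(rng.integers(0, W - gw))
            y = int(rng.integers(0, H - gh))
            if bool(mask[y : y + gh, x : x + gw].any()) == want_overlap:
                return paste(g, x, y)
        # deterministic grid sweep before giving up on this glyph size
        candidates = [
            (x, y)
            for y in range(0, H - gh, max(gh // 2, 1))
            for x in range(0, W - gw, max(gw // 2, 1))
            if bool(mask[y : y + gh, x : x + gw].any()) == want_overlap
        ]
        if candidates:
            x, y = candidates[int(rng.integers(0, len(candidates)))]
            return paste(g, x, y)
        g = g.resize((max(gw * 2 // 3, 8), max(gh * 2 // 3, 8)), Image.BILINEAR)
    logger.info("no admissible position for %s arrow, skipped", kind)
    return (image.copy(), None) if return_spec else image.copy()
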