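"""Image-level augmentations, the 11-flag augmentation fingerprint scheme
and the distort-then-resize step."""

from __future__ import annotations

import io
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from . import annotations
from .param_space import FeatureFingerprint, FingerprintScheme, binary

__all__ = [
    "CANONICAL_OPS",
    "augmentation_scheme",
    "augmentations_from_fingerprint",
    "apply_augmentation",
    "apply_fingerprint",
    "sample_distorted_dims",
    "distort_and_resize",
    "RESIZE_METHODS",
]

#: operator order: annotations first, geometric, photometric, compression last
CANONICAL_OPS: Tuple[str, ...] = (
    "curved_arrow",
    "straight_arrow",
    "identity_label",
    "rest_group_label",
    "condition_label",
    "rotation",
    "shear",
    "salt_pepper",
    "brightness_colour",
    "jpeg_compression",
    "pixelation",
)

# parameter ranges ("mild" perturbations)
ROTATION_DEG = 5.0
SHEAR_DEG = 10.0
SALT_PEPPER_DENSITY = (0.001, 0.01)
BRIGHTNESS_RANGE = (0.7, 1.3)
CHANNEL_JITTER = 0.10
JPEG_QUALITY = (40, 95)
PIXELATION_FACTOR = (1.5, 3.0)

RESIZE_METHODS = {
    "nearest": Image.NEAREST,
    "bilinear": Image.BILINEAR,
    "bicubic": Image.BICUBIC,
    "area": Image.BOX,
    "lanczos": Image.LANCZOS,
}

_scheme_cache: Optional[FingerprintScheme] = None


def augmentation_scheme() -> FingerprintScheme:
    """11 binary presence/absence flags; 2^11 = 2048 valid fingerprints."""
    global _scheme_cache
    if _scheme_cache is None:
        scheme = FingerprintScheme((), "AUGMENT")
        for op in CANONICAL_OPS:
            scheme = FingerprintScheme(scheme.decisions + (binary(op),), "AUGMENT")
        _scheme_cache = scheme
    return _scheme_cache


def augmentations_from_fingerprint(fp: Sequence[int]) -> List[str]:
    """Operator ids whose flag is set, in canonical order."""
    bits = fp.bits if isinstance(fp, FeatureFingerprint) else tuple(fp)
    if len(bits) != len(CANONICAL_OPS):
        raise ValueError(
            f"augmentation fingerprint must have {len(CANONICAL_OPS)} bits, "
            f"got {len(bits)}"
        )
    return [op for op, bit in zip(CANONICAL_OPS, bits) if bit]


# ---------------------------------------------------------------------------
# operators


def _rotate(img: Image.Image, rng: np.random.Generator) -> Image.Image:
    angle = float(rng.uniform(-ROTATION_DEG, ROTATION_DEG))
    return img.rotate(angle, resample=Image.BILINEAR, fillcolor=(255, 255, 255))


def _shear(img: Image.Image, rng: np.random.Generator) -> Image.Image:
    shear = np.tan(np.radians(float(rng.uniform(-SHEAR_DEG, SHEAR_DEG))))
    w, h = img.size
    # shear about the image centre so content stays put
    coeffs = (1.0, shear, -shear * h / 2, 0.0, 1.0, 0.0)
    return img.transform(
        (w, h), Image.AFFINE, coeffs, resample=Image.BILINEAR,
        fillcolor=(255, 255, 255),
    )


def _salt_pepper(img: Image.Image, rng: np.random.Generator) -> Image.Image:
    arr = np.asarray(img.convert("RGB")).copy()
    h, w = arr.shape[:2]
    density = float(rng.uniform(*SALT_PEPPER_DENSITY))
    n = max(int(density * h * w), 1)
    ys = rng.integers(0, h, size=n)
    xs = rng.integers(0, w, size=n)
    vals = rng.integers(0, 2, size=n) * 255
    arr[ys, xs] = vals[:, None]
    return Image.fromarray(arr)


def _brightness_colour(img: Image.Image, rng: np.random.Generator) -> Image.Image:
    arr = np.asarray(img.convert("RGB")).astype(np.float32)
    factor = float(rng.uniform(*BRIGHTNESS_RANGE))
    jitter = rng.uniform(1 - CHANNEL_JITTER, 1 + CHANNEL_JITTER, size=3)
    arr = arr * factor * jitter[None, None, :]
    return Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8))


def _jpeg(img: Image.Image, rng: np.random.Generator) -> Image.Image:
    quality = int(rng.integers(JPEG_QUALITY[0], JPEG_QUALITY[1] + 1))
    buf = io.BytesIO()
    img.convert("RGB").save(buf, format="JPEG", quality=quality)
    buf.seek(0)
    return Image.open(buf).convert("RGB")


def _pixelate(img: Image.Image, rng: np.random.Generator) -> Image.Image:
    factor = float(rng.uniform(*PIXELATION_FACTOR))
    w, h = img.size
    small = img.resize(
        (max(int(w / factor), 1), max(int(h / factor), 1)), Image.NEAREST
    )
    return small.resize((w, h), Image.NEAREST)


def _annotation_op(kind: str) -> Callable[[Image.Image, np.random.Generator], Image.Image]:
    def op(img: Image.Image, rng: np.random.Generator) -> Image.Image:
        mask = annotations.structure_mask(img)
        if kind in ("curved_arrow", "straight_arrow"):
            return annotations.place_arrow(img, kind.split("_")[0], mask, rng)
        gen = {
            "identity_label": annotations.gen_identity_label,
            "rest_group_label": annotations.gen_rest_group_label,
            "condition_label": annotations.gen_reaction_condition_label,
        }[kind]
        return annotations.place_label(img, gen(rng), mask, rng)

    return op


_OPERATORS: dict = {
    "curved_arrow": _annotation_op("curved_arrow"),
    "straight_arrow": _annotation_op("straight_arrow"),
    "identity_label": _annotation_op("identity_label"),
    "rest_group_label": _annotation_op("rest_group_label"),
    "condition_label": _annotation_op("condition_label"),
    "rotation": _rotate,
    "shear": _shear,
    "salt_pepper": _salt_pepper,
    "brightness_colour": _brightness_colour,
    "jpeg_compression": _jpeg,
    "pixelation": _pixelate,
}


def apply_augmentation(
    image: Image.Image, op_id: str, rng: np.random.Generator
) -> Image.Image:
    """Apply one operator; output dimensions always equal the input's."""
    try:
        op = _OPERATORS[op_id]
    except KeyError:
        raise ValueError(f"unknown augmentation operator {op_id!r}") from None
    out = op(image, rng)
    assert out.size == image.size
    return out


def apply_fingerprint(
    image: Image.Image, fp: Sequence[int], rng: np.random.Generator
) -> Image.Image:
    """Decode an 11-bit fingerprint and apply its operators in order."""
    for op_id in augmentations_from_fingerprint(fp):
        image = apply_augmentation(image, op_id, rng)
    return image


# ---------------------------------------------------------------------------
# distort-then-resize


def sample_distorted_dims(
    m: int, n: int, rng: np.random.Generator
) -> Tuple[int, int]:
    """Intermediate dims: uniform integers in [ceil(0.9 d), floor(1.1 d)]."""
    if m < 32 or n < 32:
        raise ValueError(f"target shape ({m}, {n}) too small; need >= 32")
    m_dist = int(rng.integers(int(np.ceil(0.9 * m)), int(np.floor(1.1 * m)) + 1))
    n_dist = int(rng.integers(int(np.ceil(0.9 * n)), int(np.floor(1.1 * n)) + 1))
    return m_dist, n_dist


def distort_and_resize(
    render_fn: Callable[[Tuple[int, int]], Image.Image],
    m: int,
    n: int,
    rng: np.random.Generator,
    return_info: bool = False,
):
    """Render at perturbed dims, then resample to (m, n) with a random method.

    ``render_fn`` receives the intermediate ``(m_dist, n_dist)`` shape and
    must return an image of that shape.
    """
    m_dist, n_dist = sample_distorted_dims(m, n, rng)
    img = render_fn((m_dist, n_dist))
    methods = sorted(RESIZE_METHODS)
    method = methods[int(rng.integers(0, len(methods)))]
    out = img.resize((n, m), RESIZE_METHODS[method])
    if return_info:
        return out, {"intermediate_shape": (m_dist, n_dist), "resize_method": method}
    return out
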