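"""User-facing generation: seeded single depictions, augmented depictions,
batch dataset generation with manifests, and systematic seed evolution.

Every pseudo-random choice derives from one initial seed through a
counter-based 64-bit mixing function, so a (SMILES list, config) pair
fully determines every output byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from . import augment, diversity
from .param_space import (
    StyleProfile,
    assignment_to_fingerprint,
    FeatureFingerprint,
    fingerprint_to_assignment,
    reference_profiles,
    sample_assignment,
)
from .rendering import parse_structure, render

__all__ = [
    "splitmix64",
    "evolve_seed",
    "SeedStream",
    "GeneratorConfig",
    "DatasetManifest",
    "DepictionGenerator",
]

logger = logging.getLogger(__name__)

_MASK64 = (1 << 64) - 1


def splitmix64(x: int) -> int:
    """64-bit avalanche mix (SplitMix64 finaliser); bijective on uint64."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def evolve_seed(state: Tuple[int, int]) -> Tuple[int, Tuple[int, int]]:
    """Return (seed, next state) for state = (initial seed, counter).

    Seeds are ``splitmix64(mix(initial) + counter)``; distinct counters map
    to distinct seeds because the mix is a bijection.
    """
    initial, counter = state
    seed = splitmix64((splitmix64(initial & _MASK64) + counter) & _MASK64)
    return seed, (initial, counter + 1)


class SeedStream:
    """Stateful wrapper around :func:`evolve_seed`."""

    def __init__(self, initial_seed: int):
        self._state = (int(initial_seed), 0)

    def next(self) -> int:
        seed, self._state = evolve_seed(self._state)
        return seed


@dataclass
class GeneratorConfig:
    shape: Tuple[int, int] = (299, 299)
    proportions: Tuple[float, float, float] = (0.55, 0.30, 0.15)
    augmented_fraction: float = 0.5
    seed: int = 42
    fingerprint_picking: bool = True
    outdir: Optional[str] = None
    per_smiles: int = 1
    backend: str = "rdkit"
    pool_cap: int = diversity.DEFAULT_POOL_CAP

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(f"style proportions must sum to 1: {self.proportions}")
        if not all(0 <= p <= 1 for p in self.proportions):
            raise ValueError(f"style proportions must be in [0, 1]: {self.proportions}")
        if not 0 <= self.augmented_fraction <= 1:
            raise ValueError(
                f"augmented fraction must be in [0, 1]: {self.augmented_fraction}"
            )


@dataclass
class DatasetManifest:
    records: List[Dict[str, Any]]
    outdir: Optional[str] = None

    def write(self, outdir: Path) -> Tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest_path = outdir / "manifest.jsonl"
        with manifest_path.open("w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        mapping_path = outdir / "mapping.tsv"
        with mapping_path.open("w") as fh:
            for rec in self.records:
                if "filename" in rec:
                    fh.write(f"{rec['filename']}\t{rec['smiles']}\n")
        return manifest_path, mapping_path


class DepictionGenerator:
    """Seeded generator of plain and augmented structure depictions."""

    def __init__(self, config: Optional[GeneratorConfig] = None, **kwargs: Any):
        if config is None:
            config = GeneratorConfig(**kwargs)
        self.config = config
        self.profiles: Dict[str, StyleProfile] = reference_profiles()
        self._stream = SeedStream(config.seed)

    # -- context-manager sugar -------------------------------------------
    def __enter__(self) -> "DepictionGenerator":
        return self

    def __exit__(self, *exc: Any) -> None:
        return None

    # -- random draws -----------------------------------------------------
    def draw_style_and_aug(self, rng: np.random.Generator) -> Tuple[str, bool]:
        """Proportion-weighted style pick plus the augmentation coin flip."""
        ids = list(self.profiles)
        style = ids[int(rng.choice(len(ids), p=np.asarray(self.config.proportions)))]
        augmented = bool(rng.random() < self.config.augmented_fraction)
        return style, augmented

    # -- single-image API -------------------------------------------------
    def random_depiction(
        self, smiles: str, shape: Optional[Tuple[int, int]] = None
    ) -> Image.Image:
        """A depiction with randomly sampled parameters, no augmentations."""
        seed = self._stream.next()
        img, _ = self._generate_random(smiles, seed, shape, augmented=False)
        return img

    def __call__(
        self, smiles: str, shape: Optional[Tuple[int, int]] = None
    ) -> Image.Image:
        """An augmented depiction (non-structural elements + perturbations)."""
        seed = self._stream.next()
        img, _ = self._generate_random(smiles, seed, shape, augmented=True)
        return img

    depict_augmented = __call__

    # -- deterministic single-record generation ---------------------------
    def _generate_random(
        self,
        smiles: str,
        seed: int,
        shape: Optional[Tuple[int, int]],
        augmented: Optional[bool],
    ) -> Tuple[Image.Image, Dict[str, Any]]:
        """Everything derived from ``seed``: style, assignment, aug bits."""
        m, n = shape or self.config.shape
        rng = np.random.default_rng(seed)
        style_id, coin = self.draw_style_and_aug(rng)
        if augmented is None:
            augmented = coin
        profile = self.profiles[style_id]
        assignment = sample_assignment(profile.scheme, rng)
        aug_fp = (
            tuple(int(b) for b in rng.integers(0, 2, size=len(augment.CANONICAL_OPS)))
            if augmented
            else None
        )
        img, info = self._render_pipeline(smiles, profile, assignment, aug_fp, (m, n), rng)
        style_fp = assignment_to_fingerprint(profile.scheme, assignment)
        info.update(
            mode="random",
            smiles=smiles,
            style_id=style_id,
            style_fingerprint=list(style_fp.bits),
            augmentation_fingerprint=list(aug_fp) if aug_fp is not None else None,
            seed=seed,
            shape=[m, n],
        )
        return img, info

    def _generate_planned(
        self,
        smiles: str,
        style_id: str,
        style_fp: Sequence[int],
        aug_fp: Optional[Sequence[int]],
        seed: int,
        shape: Optional[Tuple[int, int]] = None,
    ) -> Tuple[Image.Image, Dict[str, Any]]:
        m, n = shape or self.config.shape
        rng = np.random.default_rng(seed)
        profile = self.profiles[style_id]
        fp = FeatureFingerprint(tuple(int(b) for b in style_fp), style_id)
        assignment = fingerprint_to_assignment(profile.scheme, fp, rng)
        img, info = self._render_pipeline(smiles, profile, assignment, aug_fp, (m, n), rng)
        info.update(
            mode="fingerprint",
            smiles=smiles,
            style_id=style_id,
            style_fingerprint=[int(b) for b in style_fp],
            augmentation_fingerprint=[int(b) for b in aug_fp] if aug_fp is not None else None,
            seed=seed,
            shape=[m, n],
        )
        return img, info

    def _render_pipeline(
        self,
        smiles: str,
        profile: StyleProfile,
        assignment: Dict[str, Any],
        aug_fp: Optional[Sequence[int]],
        shape: Tuple[int, int],
        rng: np.random.Generator,
    ) -> Tuple[Image.Image, Dict[str, Any]]:
        try:
            molecule = parse_structure(smiles)
        except ValueError as exc:
            raise ValueError(f"cannot depict SMILES {smiles!r}: {exc}") from exc
        m, n = shape

        def render_at(dims: Tuple[int, int]) -> Image.Image:
            img = render(molecule, profile, assignment, dims, rng,
                         backend=self.config.backend)
            if aug_fp is not None:
                img = augment.apply_fingerprint(img, aug_fp, rng)
            return img

        img, info = augment.distort_and_resize(render_at, m, n, rng, return_info=True)
        return img, info

    def regenerate(self, record: Dict[str, Any]) -> Image.Image:
        """Rebuild the exact image a manifest record describes."""
        shape = tuple(record["shape"])
        if record["mode"] == "fingerprint":
            img, _ = self._generate_planned(
                record["smiles"], record["style_id"], record["style_fingerprint"],
                record["augmentation_fingerprint"], record["seed"], shape,
            )
        else:
            img, _ = self._generate_random(
                record["smiles"], record["seed"], shape,
                augmented=record["augmentation_fingerprint"] is not None,
            )
        return img

    # -- batch API ---------------------------------------------------------
    def batch_generate(
        self, smiles_list: Sequence[str], outdir: Optional[str] = None
    ) -> DatasetManifest:
        """Generate ``len(smiles_list) * per_smiles`` PNGs plus a manifest."""
        if not smiles_list:
            raise ValueError("empty SMILES list")
        cfg = self.config
        out = Path(outdir or cfg.outdir or ".")
        out.mkdir(parents=True, exist_ok=True)
        n_total = len(smiles_list) * cfg.per_smiles

        plan = None
        if cfg.fingerprint_picking:
            plan = diversity.plan_dataset(
                n_total, cfg.proportions, cfg.augmented_fraction,
                self.profiles, seed=cfg.seed, pool_cap=cfg.pool_cap,
            )

        stream = SeedStream(cfg.seed)
        records: List[Dict[str, Any]] = []
        n_failed = 0
        for i in range(n_total):
            smiles = smiles_list[i // cfg.per_smiles]
            seed = stream.next()
            filename = f"img_{i:06d}.png"
            try:
                if plan is not None:
                    rec = plan[i]
                    img, info = self._generate_planned(
                        smiles, rec.style_id, rec.style_fingerprint,
                        rec.augmentation_fingerprint, seed,
                    )
                else:
                    img, info = self._generate_random(smiles, seed, None, None)
                img.save(out / filename, format="PNG")
                info["index"] = i
                info["filename"] = filename
                records.append(info)
            except Exception as exc:
                n_failed += 1
                logger.error("failed to depict %r: %s", smiles, exc)
                records.append(
                    {"index": i, "smiles": smiles, "seed": seed, "error": str(exc)}
                )
        if n_failed == n_total:
            raise RuntimeError("all depictions failed")
        manifest = DatasetManifest(records, str(out))
        manifest.write(out)
        return manifest
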