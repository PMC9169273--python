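# chemdepict

Generate diverse, fully reproducible raster depictions of chemical
structures from SMILES, for training and benchmarking optical chemical
structure recognition (OCSR) systems.

Every pseudo-random drawing decision (kekulisation, bond width, font,
rotation, ...) is flagged into a **feature-fingerprint scheme**: binary
decisions take one bit, categorical decisions a one-hot span, and numeric
ranges a one-hot span over three near-equal subranges. The set of valid
fingerprints is enumerated exactly, and a greedy **MaxMin (farthest-point)
picker** under Tanimoto distance selects maximally diverse parameter
combinations. Depictions can additionally receive non-structural
annotations (identity / rest-group / reaction-condition labels, curved and
straight arrows) and image augmentations (rotation, shear, salt & pepper
noise, brightness/colour jitter, JPEG compression, pixelation), each
toggled by an 11-bit augmentation fingerprint. Images are rendered at a
randomly perturbed size and resampled to the target shape to inject
resizing artefacts.

Three built-in style profiles emulate distinct toolkit looks on one RDKit
backend:

| profile  | decisions | valid fingerprints |
|----------|-----------|--------------------|
| STYLE_A  | 15        | 2,799,360          |
| STYLE_B  | 10        | 18,432             |
| STYLE_C  | 8         | 864                |
| augmentations | 11 binary flags | 2,048 |

Dataset proportions default to 55% / 30% / 15% across the styles with 50%
of images augmented. Given the same SMILES input and initial seed, every
output byte (images and manifests) is reproduced exactly; the seed is
evolved through a counter-based 64-bit mixing function, so parallel
instances with different initial seeds produce different datasets.

## Python API

```python
from chemdepict import DepictionGenerator, GeneratorConfig

smiles = "CN1C=NC2=C1C(=O)N(C(=O)N2C)C"
with DepictionGenerator(GeneratorConfig(seed=42)) as depictor:
    image = depictor.random_depiction(smiles)   # plain depiction, 299x299
    augmented = depictor(smiles)                # + annotations & noise

manifest = depictor.batch_generate([smiles, "c1ccccc1"], outdir="out")
```

`batch_generate` writes PNGs plus `manifest.jsonl` (one self-describing
record per image: SMILES, style id, fingerprints, seed, resize method,
filename) and `mapping.tsv` (filename ↔ SMILES). Any manifest record can
be replayed bit-exactly with `depictor.regenerate(record)`.

## CLI

```bash
chemdepict input.smi --size 299 --seed 42 --num-per-smiles 1 \
    --proportions 0.55,0.30,0.15 --augmented-fraction 0.5 \
    --fingerprint-picking --outdir depictions
```

`--no-fingerprint-picking` switches to plain random parameter sampling;
`--shard i/k` processes every k-th SMILES starting at i with a shifted
seed, for manual parallelisation. `--backend stub` swaps in a fast
chemistry-light line renderer for smoke testing.

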