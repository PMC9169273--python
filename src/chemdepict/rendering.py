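"""Molecule parsing and raster rendering via pluggable style backends.

Two backends ship:

* :class:`RDKitBackend` — the real cheminformatics renderer (Cairo), used
  by all three style profiles with profile-specific parameter presets;
* :class:`StubBackend` — a minimal deterministic line renderer over the
  molecule's 2-D coordinates, for fast smoke tests and timing runs.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Any, Dict, List, Optional, Tuple

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from rdkit import Chem
from rdkit.Chem import rdAbbreviations, rdDepictor
from rdkit.Chem.Draw import rdMolDraw2D

from .param_space import StyleProfile
from .vocab import SUPERATOMS, resolve_font

__all__ = [
    "MoleculeGraph",
    "parse_structure",
    "abbreviate_substructures",
    "contracted_labels",
    "render",
    "RDKitBackend",
    "StubBackend",
    "get_backend",
]

WHITE = (255, 255, 255)

_ABBREV_DEFS = None


def _abbreviation_defs():
    # largest groups first so e.g. tBu wins over its methyl substructures;
    # bare methyl is never condensed (it would match every terminal CH3)
    global _ABBREV_DEFS
    if _ABBREV_DEFS is None:
        items = sorted(
            ((label, sm) for label, sm in SUPERATOMS.items() if label != "Me"),
            key=lambda kv: -len(kv[1]),
        )
        text = "\n".join(f"{label}  {smarts}" for label, smarts in items)
        _ABBREV_DEFS = rdAbbreviations.ParseAbbreviations(text)
    return _ABBREV_DEFS


@dataclass
class MoleculeGraph:
    """A parsed molecule plus a 2-D layout, ready for rendering."""

    mol: Chem.Mol
    smiles: str

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def atoms(self) -> List[Tuple[str, int, bool]]:
        """(element, formal charge, has-chirality-flag) per atom."""
        return [
            (
                a.GetSymbol(),
                a.GetFormalCharge(),
                a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED,
            )
            for a in self.mol.GetAtoms()
        ]

    @property
    def bonds(self) -> List[Tuple[int, int, float]]:
        """(begin, end, bond order) per bond."""
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.mol.GetBonds()
        ]

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of 2-D layout coordinates."""
        conf = self.mol.GetConformer()
        return np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y]
             for i in range(self.mol.GetNumAtoms())]
        )

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(Chem.Mol(self.mol), self.smiles)


def parse_structure(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string and assign a deterministic 2-D layout."""
    if not smiles or not smiles.strip():
        raise ValueError("empty SMILES string")
    cleaned = "".join(smiles.split())
    mol = Chem.MolFromSmiles(cleaned)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    rdDepictor.Compute2DCoords(mol)
    return MoleculeGraph(mol, cleaned)


def abbreviate_substructures(
    molecule: MoleculeGraph, rng: Optional[np.random.Generator] = None
) -> MoleculeGraph:
    """Collapse matched superatom groups into labelled pseudo-atoms.

    Molecules without any match are returned unchanged (as a copy).  The
    rng is accepted for interface symmetry; matching itself is
    deterministic.
    """
    mol = rdAbbreviations.CondenseMolAbbreviations(
        Chem.Mol(molecule.mol), _abbreviation_defs()
    )
    rdDepictor.Compute2DCoords(mol)
    return MoleculeGraph(mol, molecule.smiles)


def contracted_labels(molecule: MoleculeGraph) -> List[str]:
    """Labels of pseudo-atoms produced by abbreviation, in atom order."""
    out = []
    for atom in molecule.mol.GetAtoms():
        if atom.HasProp("atomLabel"):
            out.append(atom.GetProp("atomLabel"))
    return out


class RDKitBackend:
    """Cairo renderer; maps assignment values onto RDKit draw options."""

    id = "rdkit"

    def render(
        self,
        molecule: MoleculeGraph,
        assignment: Dict[str, Any],
        shape: Tuple[int, int],
        rng: np.random.Generator,
    ) -> Image.Image:
        m, n = shape
        mol = Chem.Mol(molecule.mol)
        if assignment.get("abbreviate_substructures"):
            mol = rdAbbreviations.CondenseMolAbbreviations(mol, _abbreviation_defs())
        kekulize = bool(assignment.get("kekulised", 1))
        try:
            mol = rdMolDraw2D.PrepareMolForDrawing(mol, kekulize=kekulize)
        except Chem.KekulizeException:
            mol = rdMolDraw2D.PrepareMolForDrawing(mol, kekulize=False)
        rdDepictor.Compute2DCoords(mol)

        drawer = rdMolDraw2D.MolDraw2DCairo(n, m)
        opts = drawer.drawOptions()
        opts.rotate = float(assignment.get("rotation", 0))
        opts.bondLineWidth = int(assignment.get("line_thickness", 2))
        if "font_size" in assignment:
            opts.fixedFontSize = int(assignment["font_size"])
        if "bond_length" in assignment:
            opts.fixedBondLength = float(assignment["bond_length"])
        if "label_distance" in assignment:
            opts.additionalAtomLabelPadding = float(assignment["label_distance"]) / 100.0
        if "padding" in assignment:
            opts.padding = float(assignment["padding"])
        opts.addAtomIndices = bool(assignment.get("atom_numbering", 0))
        opts.addBondIndices = bool(assignment.get("bond_numbering", 0))
        opts.addStereoAnnotation = bool(assignment.get("chirality_labels", 0))
        opts.explicitMethyl = bool(assignment.get("explicit_methyl", 0))
        opts.singleColourWedgeBonds = bool(assignment.get("single_colour_wedges", 0))
        if assignment.get("black_and_white"):
            opts.useBWAtomPalette()
        if "font_type" in assignment:
            font = resolve_font(str(assignment["font_type"]))
            if font:
                opts.fontFile = font

        drawer.DrawMolecule(mol)
        drawer.FinishDrawing()
        png = drawer.GetDrawingText()
        return Image.open(io.BytesIO(png)).convert("RGB")


class StubBackend:
    """Deterministic skeleton renderer drawing bonds as plain PIL lines.

    Honours rotation, line thickness, font size and atom numbering; ignores
    chemistry-specific options.  Intended for CI smoke tests and timing.
    """

    id = "stub"

    def render(
        self,
        molecule: MoleculeGraph,
        assignment: Dict[str, Any],
        shape: Tuple[int, int],
        rng: np.random.Generator,
    ) -> Image.Image:
        m, n = shape
        img = Image.new("RGB", (n, m), WHITE)
        draw = ImageDraw.Draw(img)

        coords = molecule.coords.copy()
        if coords.shape[0] == 0:
            return img
        centroid = coords.mean(axis=0)
        theta = math.radians(float(assignment.get("rotation", 0)))
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        coords = (coords - centroid) @ rot.T

        span = coords.max(axis=0) - coords.min(axis=0)
        scale = 0.85 * min(n, m) / max(span.max(), 1e-6)
        coords = coords * scale
        coords[:, 1] *= -1  # image y grows downward
        coords += np.array([n / 2, m / 2]) - coords.mean(axis=0)

        width = int(assignment.get("line_thickness", 2))
        for i, j, order in molecule.bonds:
            p, q = coords[i], coords[j]
            d = q - p
            norm = np.hypot(*d) or 1.0
            perp = np.array([-d[1], d[0]]) / norm * (width + 2)
            for k in range(int(order)):
                off = perp * (k - (int(order) - 1) / 2)
                draw.line(
                    [tuple(p + off), tuple(q + off)], fill=(0, 0, 0), width=width
                )

        font_size = int(assignment.get("font_size", 14))
        try:
            font = ImageFont.load_default(size=font_size)
        except TypeError:  # older pillow
            font = ImageFont.load_default()
        for idx, (sym, charge, _chiral) in enumerate(molecule.atoms):
            x, y = coords[idx]
            if sym != "C":
                draw.text((x - 4, y - 6), sym, fill=(0, 0, 128), font=font)
            if assignment.get("atom_numbering"):
                draw.text((x + 3, y + 3), str(idx), fill=(64, 64, 64), font=font)
        return img


_BACKENDS = {"rdkit": RDKitBackend(), "stub": StubBackend()}


def get_backend(backend_id: str):
    try:
        return _BACKENDS[backend_id]
    except KeyError:
        raise ValueError(f"unknown backend {backend_id!r}") from None


def render(
    molecule: MoleculeGraph,
    style: StyleProfile,
    assignment: Dict[str, Any],
    shape: Tuple[int, int],
    rng: np.random.Generator,
    backend: str = "rdkit",
) -> Image.Image:
    """Render a molecule under a style profile's parameter assignment.

    Returns an RGB image of exactly ``shape``; deterministic given
    (molecule, assignment, rng seed).  The input molecule is never mutated.
    """
    be = get_backend(backend)
    try:
        img = be.render(molecule, assignment, shape, rng)
    except Exception as exc:
        raise RuntimeError(
            f"backend {be.id!r} failed for style {style.id!r} "
            f"with assignment {assignment!r}: {exc}"
        ) from exc
    if img.size != (shape[1], shape[0]):
        img = img.resize((shape[1], shape[0]), Image.LANCZOS)
    return img
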