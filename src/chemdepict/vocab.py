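"""Shipped vocabularies: superatom abbreviations, reagents, solvents, fonts.

Fonts are discovered at import time from matplotlib's bundled TTF
directory so that the package stays text-only; if none are found the
renderers fall back to their default fonts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

__all__ = [
    "SUPERATOMS",
    "SUPERATOM_LABELS",
    "REAGENTS",
    "SOLVENTS",
    "REST_GROUP_VARIABLES",
    "available_font_files",
    "resolve_font",
]

#: abbreviation label -> attachment SMARTS (dummy atom marks the bond)
SUPERATOMS: Dict[str, str] = {
    "Me": "*C",
    "Et": "*CC",
    "Pr": "*CCC",
    "iPr": "*C(C)C",
    "nBu": "*CCCC",
    "tBu": "*C(C)(C)C",
    "Ph": "*c1ccccc1",
    "Bn": "*Cc1ccccc1",
    "Bz": "*C(=O)c1ccccc1",
    "Ac": "*C(C)=O",
    "OMe": "*OC",
    "OEt": "*OCC",
    "CF3": "*C(F)(F)F",
    "CCl3": "*C(Cl)(Cl)Cl",
    "CN": "*C#N",
    "NO2": "*[N+](=O)[O-]",
    "CO2H": "*C(=O)O",
    "CO2Me": "*C(=O)OC",
    "SO3H": "*S(=O)(=O)O",
    "NMe2": "*N(C)C",
    "OBn": "*OCc1ccccc1",
    "OAc": "*OC(C)=O",
    "Boc": "*C(=O)OC(C)(C)C",
    "Cbz": "*C(=O)OCc1ccccc1",
    "TMS": "*[Si](C)(C)C",
}

SUPERATOM_LABELS: List[str] = list(SUPERATOMS)

REAGENTS: List[str] = [
    "NaOH", "KOH", "HCl", "H2SO4", "NaBH4", "LiAlH4", "Pd/C", "H2",
    "NaH", "K2CO3", "Et3N", "DIPEA", "DCC", "EDC", "DMAP", "TFA",
    "n-BuLi", "MeMgBr", "SOCl2", "PPh3", "mCPBA", "AcOH",
]

SOLVENTS: List[str] = [
    "EtOH", "MeOH", "H2O", "THF", "DCM", "DMF", "DMSO", "toluene",
    "Et2O", "MeCN", "EtOAc", "dioxane",
]

REST_GROUP_VARIABLES: List[str] = ["R", "R'", "X", "Y", "Z"]

_font_cache: Optional[List[str]] = None


def available_font_files() -> List[str]:
    """Sorted TTF paths probed from matplotlib's bundled font directory."""
    global _font_cache
    if _font_cache is None:
        try:
            import matplotlib

            ttf_dir = Path(matplotlib.get_data_path()) / "fonts" / "ttf"
            _font_cache = sorted(str(p) for p in ttf_dir.glob("*.ttf"))
        except Exception:
            _font_cache = []
    return _font_cache


def resolve_font(font_id: str) -> Optional[str]:
    """Map a ``font_NN`` option to a concrete TTF path (None = default font)."""
    fonts = available_font_files()
    if not fonts:
        return None
    try:
        idx = int(font_id.split("_")[-1])
    except (ValueError, IndexError):
        return None
    return fonts[idx % len(fonts)]
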