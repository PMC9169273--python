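"""Depiction-parameter spaces and one-hot feature-fingerprint schemes.

A depiction style is described by an ordered list of flagged random
decisions.  Each decision contributes a *building block* — the set of bit
patterns it may legally write into its span of the fingerprint:

* binary decisions occupy one position and contribute ``(0,)`` / ``(1,)``;
* categorical decisions with *k* options occupy *k* positions and
  contribute the *k* one-hot patterns;
* numeric-range decisions occupy three positions, each bound to one of
  three near-equal subranges of the declared range.

The set of valid fingerprints is the cartesian product of the building
blocks, concatenated in layout order.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Any, Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ParameterDecision",
    "FingerprintScheme",
    "FeatureFingerprint",
    "StyleProfile",
    "binary",
    "categorical",
    "int_range",
    "real_range",
    "register_decision",
    "building_blocks",
    "ranged_subranges",
    "count_valid_fingerprints",
    "enumerate_valid_fingerprints",
    "fingerprint_at_index",
    "sample_assignment",
    "fingerprint_to_assignment",
    "assignment_to_fingerprint",
    "validate_fingerprint",
    "scheme_to_json",
    "scheme_from_json",
    "style_a_profile",
    "style_b_profile",
    "style_c_profile",
    "reference_profiles",
]

BINARY = "binary"
CATEGORICAL = "categorical"
RANGED = "ranged"

#: number of subranges a numeric range is split into
N_SUBRANGES = 3


@dataclass(frozen=True)
class ParameterDecision:
    """One flagged random choice made during depiction creation."""

    name: str
    kind: str
    options: Tuple[Any, ...] = ()
    low: Optional[float] = None
    high: Optional[float] = None
    integer: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("decision name must be non-empty")
        if self.kind == BINARY:
            pass
        elif self.kind == CATEGORICAL:
            if len(self.options) < 2:
                raise ValueError(
                    f"categorical decision {self.name!r} needs >= 2 options, "
                    f"got {len(self.options)}"
                )
            if len(set(self.options)) != len(self.options):
                raise ValueError(f"duplicate options in decision {self.name!r}")
        elif self.kind == RANGED:
            if self.low is None or self.high is None or not (self.low < self.high):
                raise ValueError(
                    f"ranged decision {self.name!r} needs low < high, "
                    f"got [{self.low}, {self.high}]"
                )
            if self.integer:
                lo, hi = int(self.low), int(self.high)
                if hi - lo + 1 < N_SUBRANGES:
                    raise ValueError(
                        f"integer range of {self.name!r} must span >= "
                        f"{N_SUBRANGES} values"
                    )
        else:
            raise ValueError(f"unknown decision kind {self.kind!r}")

    @property
    def span_width(self) -> int:
        """Number of fingerprint positions this decision occupies."""
        if self.kind == BINARY:
            return 1
        if self.kind == CATEGORICAL:
            return len(self.options)
        return N_SUBRANGES

    @property
    def n_blocks(self) -> int:
        """Number of valid building blocks."""
        if self.kind == BINARY:
            return 2
        if self.kind == CATEGORICAL:
            return len(self.options)
        return N_SUBRANGES


def binary(name: str) -> ParameterDecision:
    return ParameterDecision(name, BINARY)


def categorical(name: str, options: Sequence[Any]) -> ParameterDecision:
    return ParameterDecision(name, CATEGORICAL, options=tuple(options))


def int_range(name: str, low: int, high: int) -> ParameterDecision:
    return ParameterDecision(name, RANGED, low=low, high=high, integer=True)


def real_range(name: str, low: float, high: float) -> ParameterDecision:
    return ParameterDecision(name, RANGED, low=low, high=high, integer=False)


@dataclass(frozen=True)
class FingerprintScheme:
    """Ordered layout of decisions onto contiguous fingerprint spans."""

    decisions: Tuple[ParameterDecision, ...] = ()
    scheme_id: str = "scheme"

    def __post_init__(self) -> None:
        names = [d.name for d in self.decisions]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate decision names in scheme: {names}")

    @property
    def layout(self) -> Tuple[Tuple[int, int], ...]:
        """Per-decision half-open position spans ``(start, stop)``."""
        spans = []
        pos = 0
        for d in self.decisions:
            spans.append((pos, pos + d.span_width))
            pos += d.span_width
        return tuple(spans)

    @property
    def total_length(self) -> int:
        return sum(d.span_width for d in self.decisions)

    def decision(self, name: str) -> ParameterDecision:
        for d in self.decisions:
            if d.name == name:
                return d
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.decisions)


@dataclass(frozen=True)
class FeatureFingerprint:
    """Fixed-length bit array; one valid building block per decision span."""

    bits: Tuple[int, ...]
    scheme_id: str = "scheme"

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("fingerprint bits must be 0 or 1")

    def __len__(self) -> int:
        return len(self.bits)


def register_decision(
    scheme: FingerprintScheme, decision: ParameterDecision
) -> FingerprintScheme:
    """Return ``scheme`` extended by ``decision`` (layout span appended)."""
    if any(d.name == decision.name for d in scheme.decisions):
        raise ValueError(f"decision {decision.name!r} already registered")
    return FingerprintScheme(scheme.decisions + (decision,), scheme.scheme_id)


def ranged_subranges(decision: ParameterDecision) -> List[Tuple[float, float]]:
    """Inclusive subrange bounds for a ranged decision, in block order.

    Integer ranges are split into three near-equal runs with the remainder
    going to the last run; real ranges are split into exact thirds.
    """
    if decision.kind != RANGED:
        raise ValueError(f"decision {decision.name!r} is not ranged")
    if decision.integer:
        lo, hi = int(decision.low), int(decision.high)
        n = hi - lo + 1
        base = n // N_SUBRANGES
        bounds = []
        start = lo
        for i in range(N_SUBRANGES):
            size = base if i < N_SUBRANGES - 1 else n - base * (N_SUBRANGES - 1)
            bounds.append((start, start + size - 1))
            start += size
        return bounds
    lo, hi = float(decision.low), float(decision.high)
    w = (hi - lo) / N_SUBRANGES
    return [(lo + i * w, lo + (i + 1) * w) for i in range(N_SUBRANGES)]


def building_blocks(decision: ParameterDecision) -> List[Tuple[int, ...]]:
    """Ordered list of valid bit patterns for one decision span."""
    if decision.kind == BINARY:
        return [(0,), (1,)]
    k = decision.span_width
    return [tuple(1 if j == i else 0 for j in range(k)) for i in range(k)]


def count_valid_fingerprints(scheme: FingerprintScheme) -> int:
    """Product of per-decision building-block counts (1 for an empty scheme)."""
    return math.prod(d.n_blocks for d in scheme.decisions)


def enumerate_valid_fingerprints(
    scheme: FingerprintScheme, guard: int = 1_000_000
) -> List[FeatureFingerprint]:
    """All valid fingerprints, lexicographic over block indices in layout order.

    Refuses to materialise more than ``guard`` fingerprints.
    """
    n = count_valid_fingerprints(scheme)
    if n > guard:
        raise ValueError(
            f"scheme {scheme.scheme_id!r} has {n} valid fingerprints, "
            f"exceeding the guard of {guard}"
        )
    blocks = [building_blocks(d) for d in scheme.decisions]
    out = []
    for combo in itertools.product(*blocks):
        bits = tuple(itertools.chain.from_iterable(combo))
        out.append(FeatureFingerprint(bits, scheme.scheme_id))
    return out


def fingerprint_at_index(scheme: FingerprintScheme, index: int) -> FeatureFingerprint:
    """Decode enumeration position ``index`` without materialising the product.

    Matches the ordering of :func:`enumerate_valid_fingerprints` (last
    decision varies fastest).
    """
    n = count_valid_fingerprints(scheme)
    if not 0 <= index < n:
        raise IndexError(f"index {index} out of range for {n} fingerprints")
    radices = [d.n_blocks for d in scheme.decisions]
    digits = [0] * len(radices)
    for i in range(len(radices) - 1, -1, -1):
        index, digits[i] = divmod(index, radices[i])
    bits: List[int] = []
    for d, digit in zip(scheme.decisions, digits):
        bits.extend(building_blocks(d)[digit])
    return FeatureFingerprint(tuple(bits), scheme.scheme_id)


def _draw_value(decision: ParameterDecision, rng: np.random.Generator) -> Any:
    if decision.kind == BINARY:
        return int(rng.integers(0, 2))
    if decision.kind == CATEGORICAL:
        return decision.options[int(rng.integers(0, len(decision.options)))]
    if decision.integer:
        return int(rng.integers(int(decision.low), int(decision.high) + 1))
    return float(rng.uniform(decision.low, decision.high))


def sample_assignment(
    scheme: FingerprintScheme, rng: np.random.Generator
) -> Dict[str, Any]:
    """Uniform independent draw per decision; repeatable under a fixed rng."""
    return {d.name: _draw_value(d, rng) for d in scheme.decisions}


def validate_fingerprint(scheme: FingerprintScheme, fp: FeatureFingerprint) -> None:
    """Raise ``ValueError`` naming the offending decision on any bad span."""
    if len(fp.bits) != scheme.total_length:
        raise ValueError(
            f"fingerprint length {len(fp.bits)} != scheme length "
            f"{scheme.total_length}"
        )
    for d, (start, stop) in zip(scheme.decisions, scheme.layout):
        span = fp.bits[start:stop]
        if d.kind == BINARY:
            continue
        if sum(span) != 1:
            raise ValueError(
                f"span of decision {d.name!r} must be one-hot, got {span}"
            )


def fingerprint_to_assignment(
    scheme: FingerprintScheme,
    fp: FeatureFingerprint,
    rng: np.random.Generator,
) -> Dict[str, Any]:
    """Concrete parameter values for a valid fingerprint.

    Binary spans map to their bit, categorical spans to the hot option, and
    ranged spans to a uniform draw inside the hot subrange only.
    """
    validate_fingerprint(scheme, fp)
    out: Dict[str, Any] = {}
    for d, (start, stop) in zip(scheme.decisions, scheme.layout):
        span = fp.bits[start:stop]
        if d.kind == BINARY:
            out[d.name] = span[0]
        elif d.kind == CATEGORICAL:
            out[d.name] = d.options[span.index(1)]
        else:
            lo, hi = ranged_subranges(d)[span.index(1)]
            if d.integer:
                out[d.name] = int(rng.integers(int(lo), int(hi) + 1))
            else:
                out[d.name] = float(rng.uniform(lo, hi))
    return out


def assignment_to_fingerprint(
    scheme: FingerprintScheme, assignment: Dict[str, Any]
) -> FeatureFingerprint:
    """Inverse mapping: concrete values -> fingerprint bits."""
    bits: List[int] = []
    for d in scheme.decisions:
        if d.name not in assignment:
            raise ValueError(f"assignment missing decision {d.name!r}")
        v = assignment[d.name]
        if d.kind == BINARY:
            if v not in (0, 1):
                raise ValueError(f"binary value of {d.name!r} must be 0/1, got {v!r}")
            bits.append(int(v))
        elif d.kind == CATEGORICAL:
            if v not in d.options:
                raise ValueError(f"{v!r} is not an option of {d.name!r}")
            idx = d.options.index(v)
            bits.extend(1 if j == idx else 0 for j in range(len(d.options)))
        else:
            if not (d.low <= v <= d.high):
                raise ValueError(
                    f"value {v!r} of {d.name!r} outside [{d.low}, {d.high}]"
                )
            subs = ranged_subranges(d)
            idx = None
            for i, (lo, hi) in enumerate(subs):
                if lo <= v <= hi:
                    idx = i
                    break
            if idx is None:  # real-range float landing exactly on a seam
                idx = N_SUBRANGES - 1
            bits.extend(1 if j == idx else 0 for j in range(N_SUBRANGES))
    return FeatureFingerprint(tuple(bits), scheme.scheme_id)


# ---------------------------------------------------------------------------
# serialization

def scheme_to_json(scheme: FingerprintScheme) -> str:
    doc = {
        "scheme_id": scheme.scheme_id,
        "total_length": scheme.total_length,
        "decisions": [
            {
                "name": d.name,
                "kind": d.kind,
                "options": list(d.options) if d.kind == CATEGORICAL else None,
                "low": d.low,
                "high": d.high,
                "integer": d.integer,
                "span": list(span),
            }
            for d, span in zip(scheme.decisions, scheme.layout)
        ],
    }
    return json.dumps(doc, indent=2)


def scheme_from_json(text: str) -> FingerprintScheme:
    doc = json.loads(text)
    decisions = []
    for rec in doc["decisions"]:
        kind = rec["kind"]
        if kind == BINARY:
            decisions.append(binary(rec["name"]))
        elif kind == CATEGORICAL:
            decisions.append(categorical(rec["name"], rec["options"]))
        else:
            d = ParameterDecision(
                rec["name"], RANGED, low=rec["low"], high=rec["high"],
                integer=rec["integer"],
            )
            decisions.append(d)
    return FingerprintScheme(tuple(decisions), doc["scheme_id"])


# ---------------------------------------------------------------------------
# reference style profiles

@dataclass(frozen=True)
class StyleProfile:
    """A named depiction style together with its fingerprint scheme."""

    id: str
    scheme: FingerprintScheme


def _font_options(k: int) -> List[str]:
    return [f"font_{i:02d}" for i in range(k)]


def _build_scheme(scheme_id: str, decisions: Sequence[ParameterDecision]) -> FingerprintScheme:
    scheme = FingerprintScheme((), scheme_id)
    for d in decisions:
        scheme = register_decision(scheme, d)
    return scheme


def style_a_profile() -> StyleProfile:
    """Richest style: 15 decisions, 2,799,360 valid fingerprints."""
    decisions = [
        binary("kekulised"),
        binary("abbreviate_substructures"),
        binary("atom_numbering"),
        binary("chirality_labels"),
        binary("black_and_white"),
        binary("bond_numbering"),
        binary("explicit_methyl"),
        binary("single_colour_wedges"),
        int_range("bond_length", 15, 44),
        int_range("line_thickness", 1, 6),
        int_range("font_size", 12, 29),
        int_range("rotation", 0, 359),
        int_range("label_distance", 0, 14),
        real_range("padding", 0.02, 0.2),
        categorical("font_type", _font_options(15)),
    ]
    return StyleProfile("STYLE_A", _build_scheme("STYLE_A", decisions))


def style_b_profile() -> StyleProfile:
    """Mid-size style: 10 decisions, 18,432 valid fingerprints."""
    decisions = [
        binary("kekulised"),
        binary("abbreviate_substructures"),
        binary("atom_numbering"),
        binary("chirality_labels"),
        binary("black_and_white"),
        binary("bond_numbering"),
        binary("explicit_methyl"),
        int_range("line_thickness", 1, 6),
        int_range("rotation", 0, 359),
        categorical("font_type", _font_options(16)),
    ]
    return StyleProfile("STYLE_B", _build_scheme("STYLE_B", decisions))


def style_c_profile() -> StyleProfile:
    """Lean style: 8 decisions, 864 valid fingerprints."""
    decisions = [
        binary("kekulised"),
        binary("abbreviate_substructures"),
        binary("atom_numbering"),
        binary("chirality_labels"),
        binary("black_and_white"),
        int_range("line_thickness", 1, 6),
        int_range("font_size", 12, 29),
        int_range("rotation", 0, 359),
    ]
    return StyleProfile("STYLE_C", _build_scheme("STYLE_C", decisions))


def reference_profiles() -> Dict[str, StyleProfile]:
    """The three built-in style profiles, keyed by id."""
    profiles = [style_a_profile(), style_b_profile(), style_c_profile()]
    return {p.id: p for p in profiles}
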