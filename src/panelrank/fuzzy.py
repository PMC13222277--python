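"""Triangular fuzzy numbers and linguistic rating scales.

Expert judgments elicited on five-point Likert scales are mapped to
triangular fuzzy numbers (TFNs) on a 1-9 magnitude scale so that the
uncertainty of a linguistic rating is carried through aggregation,
weighting and ranking instead of being collapsed to a point score at
elicitation time.  A TFN ``(l, m, u)`` has membership rising linearly
from ``l`` to a peak at ``m`` and falling back to zero at ``u``.

Only the arithmetic the screening/ranking pipeline needs is provided:
centroid defuzzification, the component-wise product used for expert
weighting, and the vertex (root-mean-square) distance used to measure
closeness to the fuzzy ideal solutions.  General fuzzy-set algebra
(alpha-cuts, extension principle, non-triangular memberships) is out of
scope.
"""

from __future__ import annotations

import json
import math
import numbers
from dataclasses import dataclass
from typing import Iterator, Mapping

import yaml

__all__ = [
    "TriangularFuzzyNumber",
    "LinguisticScale",
    "tfn_from_likert",
    "defuzzify_centroid",
    "tfn_product",
    "vertex_distance",
    "RELEVANCE_SCALE",
    "APPLICABILITY_SCALE",
    "INVOLVEMENT_SCALE",
    "DEFAULT_SCALES",
]


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Immutable triangular fuzzy number ``(l, m, u)`` with ``0 <= l <= m <= u``.

    Construction validates the ordering invariant eagerly and rejects
    violations rather than silently re-sorting: a mis-ordered triple is
    almost always an upstream bug and re-sorting would mask it.
    """

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        for name in ("l", "m", "u"):
            v = getattr(self, name)
            if not isinstance(v, numbers.Real) or isinstance(v, bool):
                raise TypeError(f"TFN component {name} must be numeric, got {v!r}")
            if not math.isfinite(v):
                raise ValueError(f"TFN component {name} must be finite, got {v!r}")
        if self.l < 0:
            raise ValueError(f"TFN components must be non-negative, got l={self.l}")
        if not (self.l <= self.m <= self.u):
            raise ValueError(
                f"TFN ordering violated: need l <= m <= u, got ({self.l}, {self.m}, {self.u})"
            )

    def __iter__(self) -> Iterator[float]:
        yield self.l
        yield self.m
        yield self.u

    def astuple(self) -> tuple[float, float, float]:
        return (self.l, self.m, self.u)

    @property
    def centroid(self) -> float:
        """Center-of-gravity defuzzification, ``(l + m + u) / 3``."""
        return defuzzify_centroid(self)

    def __mul__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return tfn_product(self, other)

    def __repr__(self) -> str:  # compact, the dataclass default is noisy in tables
        return f"TFN({self.l:g}, {self.m:g}, {self.u:g})"


#: Short alias used throughout the package.
TFN = TriangularFuzzyNumber


def defuzzify_centroid(t: TriangularFuzzyNumber) -> float:
    """Collapse a TFN to its center of gravity.

    Computed as ``((u - l) + (m - l)) / 3 + l``, which is algebraically
    ``(l + m + u) / 3``; the result always lies within ``[l, u]`` and
    equals ``m`` for symmetric TFNs.
    """
    return ((t.u - t.l) + (t.m - t.l)) / 3.0 + t.l


def tfn_product(a: TriangularFuzzyNumber, b: TriangularFuzzyNumber) -> TriangularFuzzyNumber:
    """Component-wise product of two non-negative TFNs.

    This is the multiplication used to apply expert weights to a
    normalized decision matrix.  For internally ordered non-negative
    operands the result is again ordered.
    """
    return TriangularFuzzyNumber(a.l * b.l, a.m * b.m, a.u * b.u)


def vertex_distance(x: TriangularFuzzyNumber, z: TriangularFuzzyNumber) -> float:
    """Vertex-method distance: RMS difference of the three components.

    ``sqrt((1/3) * ((l_x - l_z)^2 + (m_x - m_z)^2 + (u_x - u_z)^2))``.
    Symmetric, non-negative, zero iff the TFNs coincide, and satisfies
    the triangle inequality (it is a Euclidean metric on R^3 up to a
    constant factor).
    """
    return math.sqrt(
        ((x.l - z.l) ** 2 + (x.m - z.m) ** 2 + (x.u - z.u) ** 2) / 3.0
    )


@dataclass(frozen=True)
class LinguisticScale:
    """Ordered mapping from Likert levels 1..5 to TFNs, with linguistic terms.

    The three panel scales (relevance, applicability, involvement) share
    the same numeric 1-9 mapping by default; they are nevertheless kept
    as named objects so an alternative calibration for one dimension can
    be configured without touching the others.
    """

    name: str
    levels: tuple[TriangularFuzzyNumber, ...]
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != 5 or len(self.terms) != 5:
            raise ValueError(
                f"scale {self.name!r} must define exactly five levels/terms, "
                f"got {len(self.levels)}/{len(self.terms)}"
            )
        modes = [t.m for t in self.levels]
        if any(b <= a for a, b in zip(modes, modes[1:])):
            raise ValueError(
                f"scale {self.name!r} modal values must be strictly increasing, got {modes}"
            )

    def __getitem__(self, level: int) -> TriangularFuzzyNumber:
        return tfn_from_likert(level, self)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "levels": [
                {"level": i + 1, "term": term, "l": t.l, "m": t.m, "u": t.u}
                for i, (term, t) in enumerate(zip(self.terms, self.levels))
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinguisticScale":
        rows = sorted(d["levels"], key=lambda r: r["level"])
        if [r["level"] for r in rows] != [1, 2, 3, 4, 5]:
            raise ValueError(
                f"scale levels must be exactly 1..5, got {[r['level'] for r in rows]}"
            )
        return cls(
            name=d["name"],
            levels=tuple(TriangularFuzzyNumber(r["l"], r["m"], r["u"]) for r in rows),
            terms=tuple(r["term"] for r in rows),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "LinguisticScale":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinguisticScale":
        return cls.from_dict(json.loads(text))


def tfn_from_likert(level: int, scale: LinguisticScale) -> TriangularFuzzyNumber:
    """Map a Likert level 1..5 to the scale's TFN, unmodified.

    Raises
    ------
    ValueError
        If ``level`` is not an integer in 1..5; the message names the
        offending value.
    """
    if isinstance(level, bool) or not isinstance(level, (int,)):
        # accept integral floats coming from pandas without silently truncating
        if isinstance(level, float) and level.is_integer():
            level = int(level)
        else:
            raise ValueError(f"Likert level must be an integer in 1..5, got {level!r}")
    if not 1 <= level <= 5:
        raise ValueError(f"Likert level must be in 1..5, got {level}")
    return scale.levels[level - 1]


_DEFAULT_NUMERIC = (
    TriangularFuzzyNumber(1, 1, 1),
    TriangularFuzzyNumber(1, 3, 5),
    TriangularFuzzyNumber(3, 5, 7),
    TriangularFuzzyNumber(5, 7, 9),
    TriangularFuzzyNumber(7, 9, 9),
)

RELEVANCE_SCALE = LinguisticScale(
    "relevance",
    _DEFAULT_NUMERIC,
    (
        "Not very relevant",
        "Reasonably relevant",
        "Moderately relevant",
        "Very relevant",
        "Extremely relevant",
    ),
)

APPLICABILITY_SCALE = LinguisticScale(
    "applicability",
    _DEFAULT_NUMERIC,
    (
        "Very difficult to obtain",
        "Difficult to obtain",
        "Moderately accessible",
        "Easily accessible",
        "Completely accessible",
    ),
)

INVOLVEMENT_SCALE = LinguisticScale(
    "involvement",
    _DEFAULT_NUMERIC,
    (
        "No involvement",
        "Low involvement",
        "Moderate involvement",
        "High involvement",
        "Specialist in the subject",
    ),
)

DEFAULT_SCALES: dict[str, LinguisticScale] = {
    "relevance": RELEVANCE_SCALE,
    "applicability": APPLICABILITY_SCALE,
    "involvement": INVOLVEMENT_SCALE,
}
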