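"""Component-band annotations for the Amide I region and their text notation.

A deconvolved Amide I band list is written in a compact field notation such
as ``1689(m,sh)/*1628(s)``: slash-separated tokens, each a wavenumber
position followed by a parenthesized list of an optional intensity grade
(``s`` strong, ``m`` medium, ``w`` weak) and shape flags (``br`` broad,
``sh`` shoulder).  Exactly one token carries a leading ``*`` marking the
dominant band maximum (the printed convention is bold, which is not
machine-readable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "BandAnnotation",
    "BandParseError",
    "parse_band_string",
    "serialize_band_string",
]

INTENSITY_GRADES = ("s", "m", "w")
SHAPE_FLAGS = ("br", "sh")

#: Wavenumber bounds (cm^-1) of the analysis window a band may occupy.
POSITION_MIN = 1580
POSITION_MAX = 1720


class BandParseError(ValueError):
    """Raised when a band notation string is malformed."""


@dataclass(frozen=True)
class BandAnnotation:
    """One component band of an Amide I band list.

    Parameters
    ----------
    position
        Band maximum in cm^-1 (integer, within [1580, 1720]).
    intensity_grade
        ``"s"``, ``"m"`` or ``"w"``; ``None`` when the annotation carries
        only shape flags.
    shape_flags
        Subset of ``{"br", "sh"}`` (broad, shoulder).
    is_dominant
        True for the single dominant maximum of the band list.
    """

    position: int
    intensity_grade: str | None = None
    shape_flags: frozenset[str] = field(default_factory=frozenset)
    is_dominant: bool = False

    def __post_init__(self) -> None:
        if not (POSITION_MIN <= self.position <= POSITION_MAX):
            raise ValueError(
                f"band position {self.position} outside "
                f"[{POSITION_MIN}, {POSITION_MAX}] cm^-1"
            )
        if self.intensity_grade is not None and self.intensity_grade not in INTENSITY_GRADES:
            raise ValueError(f"unknown intensity grade {self.intensity_grade!r}")
        unknown = set(self.shape_flags) - set(SHAPE_FLAGS)
        if unknown:
            raise ValueError(f"unknown shape flags {sorted(unknown)}")
        object.__setattr__(self, "shape_flags", frozenset(self.shape_flags))


_TOKEN_RE = re.compile(r"^(?P<dom>\*)?(?P<pos>\d{4})(?:\((?P<attrs>[a-z,]*)\))?$")


def _parse_token(token: str) -> BandAnnotation:
    m = _TOKEN_RE.match(token)
    if m is None:
        raise BandParseError(f"malformed band token {token!r}")
    grade: str | None = None
    flags: set[str] = set()
    attrs = m.group("attrs")
    for attr in filter(None, (attrs or "").split(",")):
        if attr in INTENSITY_GRADES:
            if grade is not None:
                raise BandParseError(f"duplicate intensity grade in token {token!r}")
            grade = attr
        elif attr in SHAPE_FLAGS:
            flags.add(attr)
        else:
            raise BandParseError(f"unknown attribute {attr!r} in token {token!r}")
    return BandAnnotation(
        position=int(m.group("pos")),
        intensity_grade=grade,
        shape_flags=frozenset(flags),
        is_dominant=m.group("dom") is not None,
    )


def parse_band_string(text: str) -> list[BandAnnotation]:
    """Parse a slash-separated band list such as ``"1689(m,sh)/*1628(s)"``.

    Exactly one token must carry the leading ``*`` dominance marker.

    Raises
    ------
    BandParseError
        On empty input, a malformed token, or zero/multiple dominance
        markers.
    """
    if not text or not text.strip():
        raise BandParseError("empty band string")
    bands = [_parse_token(tok.strip()) for tok in text.strip().split("/")]
    n_dominant = sum(b.is_dominant for b in bands)
    if n_dominant != 1:
        raise BandParseError(
            f"band list {text!r} has {n_dominant} dominance markers; exactly one required"
        )
    return bands


def serialize_band_string(bands: list[BandAnnotation]) -> str:
    """Inverse of :func:`parse_band_string`."""
    if not bands:
        raise ValueError("empty band list")
    if sum(b.is_dominant for b in bands) != 1:
        raise ValueError("band list must have exactly one dominant band")
    tokens = []
    for b in bands:
        attrs = ([b.intensity_grade] if b.intensity_grade else []) + [
            f for f in SHAPE_FLAGS if f in b.shape_flags
        ]
        inner = ",".join(attrs)
        tok = f"{b.position}({inner})" if inner else f"{b.position}"
        if b.is_dominant:
            tok = "*" + tok
        tokens.append(tok)
    return "/".join(tokens)
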