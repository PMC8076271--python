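"""Amide I band-position decision rules for amyloid classification.

Secondary structure shifts the Amide I maximum (C=O stretch, 1600-1700
cm^-1) in characteristic ways: tightly packed cross-beta amyloid fibrils
absorb low, between 1611 and ~1630 cm^-1; native (non-amyloid) beta sheet
extends up to ~1643 cm^-1; alpha helix, disorder and turns sit higher.
Antiparallel oligomeric beta sheet shows a second, weaker maximum between
~1685 and 1695 cm^-1 next to a dominant band near 1630 cm^-1.

:func:`classify_bands` turns a picked band list into a fibril / oligomer /
non-amyloid call; :func:`binarize` collapses the three-way call to the
amyloid-positive flag used when scoring sequence predictors, with oligomers
counted as positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .bands import BandAnnotation

__all__ = ["RuleConfig", "SpectralCall", "classify_bands", "binarize", "classify_spectrum"]


@dataclass(frozen=True)
class RuleConfig:
    """Wavenumber windows (cm^-1) of the decision rules.

    ``fibril_upper`` is set to 1632 rather than the nominal 1630: dominant
    maxima at 1631 and 1632 appear in amyloid-positive reference spectra, in
    line with the fibril band sitting "close to" 1630.  The oligomer minor
    window opens at 1684 (a minor band at 1684 occurs in a positive
    spectrum; 1679-1681 minors occur only in negative ones).
    """

    fibril_lower: float = 1611.0
    fibril_upper: float = 1632.0
    native_beta_upper: float = 1643.0
    oligomer_minor_window: tuple[float, float] = (1684.0, 1695.0)
    #: Advisory minor/major amplitude ratio bound (the minor antiparallel
    #: band is roughly five-fold weaker); not gating, band tables carry
    #: grades rather than amplitudes.
    oligomer_ratio_max: float = 0.35

    def __post_init__(self) -> None:
        lo, hi = self.oligomer_minor_window
        if not (self.fibril_lower < self.fibril_upper < self.native_beta_upper < lo < hi):
            raise ValueError("rule windows must be ordered and non-degenerate")

    @classmethod
    def from_yaml(cls, path) -> "RuleConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "oligomer_minor_window" in raw:
            raw["oligomer_minor_window"] = tuple(raw["oligomer_minor_window"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "fibril_lower": self.fibril_lower,
            "fibril_upper": self.fibril_upper,
            "native_beta_upper": self.native_beta_upper,
            "oligomer_minor_window": list(self.oligomer_minor_window),
            "oligomer_ratio_max": self.oligomer_ratio_max,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass(frozen=True)
class SpectralCall:
    """Outcome of band-rule classification for one spectrum."""

    subtype: str  # "fibril" | "oligomer" | "non_amyloid"
    positive: bool
    dominant_position: float
    evidence: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.subtype not in ("fibril", "oligomer", "non_amyloid"):
            raise ValueError(f"bad subtype {self.subtype!r}")
        if self.positive != (self.subtype in ("fibril", "oligomer")):
            raise ValueError("positive flag inconsistent with subtype")


def classify_bands(bands: list[BandAnnotation], config: RuleConfig | None = None) -> SpectralCall:
    """Assign fibril / oligomer / non-amyloid from a picked band list.

    Rule order, with ``d`` the dominant-band position:

    1. ``fibril_lower <= d <= fibril_upper`` -> fibril (amyloid-positive);
       a minor band inside the oligomer window is recorded as
       oligomer-consistent evidence but does not change the subtype.
    2. ``fibril_upper < d <= native_beta_upper`` *and* some non-dominant
       band lies in the oligomer minor window -> oligomer (positive).
    3. otherwise -> non-amyloid (negative).

    Aromatic side-chain bands must already have been excluded upstream.

    Raises
    ------
    ValueError
        On an empty band list or a list without exactly one dominant band.
    """
    cfg = config or RuleConfig()
    if not bands:
        raise ValueError("empty band list")
    dominants = [b for b in bands if b.is_dominant]
    if len(dominants) != 1:
        raise ValueError(f"expected exactly one dominant band, got {len(dominants)}")
    dom = dominants[0]
    d = float(dom.position)
    lo, hi = cfg.oligomer_minor_window
    minor_in_window = any(
        lo <= b.position <= hi for b in bands if not b.is_dominant
    )
    evidence: list[str] = []
    if cfg.fibril_lower <= d <= cfg.fibril_upper:
        evidence.append("dominant_in_fibril_window")
        if minor_in_window:
            evidence.append("oligomer_minor_present")
        return SpectralCall("fibril", True, d, tuple(evidence))
    if cfg.fibril_upper < d <= cfg.native_beta_upper and minor_in_window:
        evidence += ["dominant_in_native_beta_window", "oligomer_minor_present"]
        return SpectralCall("oligomer", True, d, tuple(evidence))
    evidence.append("dominant_outside_amyloid_windows")
    if minor_in_window:
        evidence.append("oligomer_minor_present")
    return SpectralCall("non_amyloid", False, d, tuple(evidence))


def binarize(call) -> bool:
    """Collapse a call to the amyloid-positive flag (oligomer counts positive).

    Accepts a :class:`SpectralCall`, a canonical call string
    (``positive`` / ``negative`` / ``oligomer``) or a printed cell
    (``Yes`` / ``No`` / ``Yes*``, any case).
    """
    if isinstance(call, SpectralCall):
        return call.positive
    from .fixtures import normalize_call

    return normalize_call(call) in ("positive", "oligomer")


def classify_spectrum(
    spectrum,
    sequence: str = "",
    rule_config: RuleConfig | None = None,
    baseline_method: str = "rubberband",
    sg_window: int = 31,
    sg_polyorder: int = 2,
    prominence: float = 0.05,
) -> SpectralCall:
    """Full pipeline: baseline -> normalize -> DII -> band picking -> rules.

    ``sequence`` enables exclusion of aromatic side-chain bands (Phe 1600,
    Tyr 1616, Trp 1620 cm^-1).  Deterministic: identical input yields an
    identical call.
    """
    from . import spectra as sp

    corrected = sp.baseline_correct(spectrum, method=baseline_method)
    normalized = sp.normalize_amide_one(corrected)
    dii = sp.second_derivative(normalized, window_pts=sg_window, polyorder=sg_polyorder)
    bands = sp.pick_bands(dii, sequence=sequence, prominence=prominence)
    return classify_bands(bands, rule_config)
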