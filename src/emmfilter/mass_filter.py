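"""Match measured LC–MS feature masses against a mass index within a ppm
tolerance.

Matching is on neutral monoisotopic mass only; retention time and any MS2
payload are carried through untouched for downstream annotation tools. The
ppm convention used throughout is |observed − reference| / reference × 1e6
with the candidate (reference) mass in the denominator.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .chem_core import PROTON_MASS

__all__ = [
    "Feature",
    "IndexEntry",
    "MassIndex",
    "Match",
    "MatchResult",
    "neutral_mass",
    "ppm_difference",
    "filter_features",
]

DEFAULT_TOLERANCE_PPM = 10.0


@dataclass(frozen=True)
class Feature:
    """One measured LC–MS feature."""

    feature_id: str
    mass: float  # Da
    rt_min: float = 0.0
    polarity: str = "neutralized"  # positive | negative | neutralized
    ms2: Tuple[Tuple[float, float], ...] = ()  # (m/z, rel. intensity), pass-through

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"{self.feature_id}: measured mass must be > 0")
        if self.rt_min < 0:
            raise ValueError(f"{self.feature_id}: retention time must be >= 0")
        if self.polarity not in ("positive", "negative", "neutralized"):
            raise ValueError(f"{self.feature_id}: bad polarity {self.polarity!r}")


@dataclass(frozen=True)
class IndexEntry:
    """One indexed mass with a back-reference to its record."""

    mass: float
    record_id: str  # metabolite id or derivative canonical key
    source: str  # "model" | "derivative"
    key: str  # canonical structure key


class MassIndex:
    """Sorted mass list over model metabolites and derivatives."""

    def __init__(self, entries: Sequence[IndexEntry]):
        if not entries:
            raise ValueError("mass index is empty")
        self.entries: List[IndexEntry] = sorted(entries, key=lambda e: (e.mass, e.record_id))
        self._masses = [e.mass for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_extended_model(cls, emm, include_derivatives: bool = True) -> "MassIndex":
        entries = [
            IndexEntry(mass=m.mass, record_id=m.metabolite_id, source="model", key=m.key)
            for m in emm.model.metabolites
        ]
        if include_derivatives:
            entries += [
                IndexEntry(mass=d.mass, record_id=d.key, source="derivative", key=d.key)
                for d in emm.derivatives.values()
            ]
        return cls(entries)

    @classmethod
    def from_model(cls, model) -> "MassIndex":
        return cls(
            [
                IndexEntry(mass=m.mass, record_id=m.metabolite_id, source="model", key=m.key)
                for m in model.metabolites
            ]
        )

    def query(self, observed: float, tol_ppm: float) -> List[Tuple[IndexEntry, float]]:
        """All entries within ``tol_ppm`` of ``observed``, by binary search.

        With the reference mass in the denominator, a reference r matches
        when observed/(1 + tol·1e-6) ≤ r ≤ observed/(1 − tol·1e-6).
        """
        t = tol_ppm * 1e-6
        lo = observed / (1.0 + t)
        hi = observed / (1.0 - t) if t < 1 else float("inf")
        start = bisect_left(self._masses, lo)
        stop = bisect_right(self._masses, hi)
        out = []
        for entry in self.entries[start:stop]:
            ppm = ppm_difference(observed, entry.mass)
            if ppm <= tol_ppm:
                out.append((entry, ppm))
        return out


@dataclass
class Match:
    entry: IndexEntry
    ppm_error: float


@dataclass
class MatchResult:
    """Matches of one feature against the index."""

    feature: Feature
    matches: List[Match] = field(default_factory=list)


def neutral_mass(feature: Feature, adduct: str = "none") -> float:
    """Neutral monoisotopic mass of a feature under an adduct assumption.

    ``M+H`` subtracts and ``M−H`` adds one proton mass; ``none`` passes the
    measured value through (feature tables that were already neutralized
    upstream, the default assumption).
    """
    if adduct in ("none", None):
        value = feature.mass
    elif adduct in ("M+H", "M posH"):
        if feature.polarity == "negative":
            raise ValueError(f"{feature.feature_id}: M+H adduct on a negative-mode feature")
        value = feature.mass - PROTON_MASS
    elif adduct in ("M-H", "M−H"):
        if feature.polarity == "positive":
            raise ValueError(f"{feature.feature_id}: M-H adduct on a positive-mode feature")
        value = feature.mass + PROTON_MASS
    else:
        raise ValueError(f"unknown adduct {adduct!r}; expected M+H, M-H or none")
    if value <= 0:
        raise ValueError(
            f"{feature.feature_id}: nonpositive neutral mass {value:.6f}"
        )
    return value


def ppm_difference(observed: float, reference: float) -> float:
    """|observed − reference| / reference × 1e6."""
    if reference <= 0:
        raise ValueError("reference mass must be > 0")
    return abs(observed - reference) / reference * 1e6


def filter_features(
    features: Sequence[Feature],
    index: MassIndex,
    tol_ppm: float = DEFAULT_TOLERANCE_PPM,
    adduct: str = "none",
) -> List[MatchResult]:
    """Match every feature against the index; features with no match within
    ``tol_ppm`` are omitted from the result."""
    results = []
    for feature in features:
        observed = neutral_mass(feature, adduct)
        hits = index.query(observed, tol_ppm)
        if hits:
            results.append(
                MatchResult(
                    feature=feature,
                    matches=[Match(entry=e, ppm_error=p) for e, p in hits],
                )
            )
    return results


def match_summary(results: Sequence[MatchResult], n_features: int) -> dict:
    """Matched-feature count and percentage of all measured features."""
    matched = len(results)
    return {
        "measured_masses": n_features,
        "matched_masses": matched,
        "percent_matched": round(100.0 * matched / n_features, 2) if n_features else 0.0,
    }
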