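"""Rule-based substrate-specificity prediction.

Three independent evidence channels are kept separate, the way they are
argued in the comparative AQP literature: degenerate SDP-profile matching
for the six non-aqua substrates, Froger-position comparison against the
AqpZ (water-selective) and GlpF (glycerol-permease) exemplars, and the
ar/R-filter call for high water permeability; a fourth flag marks the
108-residue NPA spacing specific to silicon transporters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .io_formats import MISSING, Fixture, load_fixture

AQPZ_FROGER = ("A", "S", "A", "F", "W")
GLPF_FROGER = ("Y", "D", "K", "P", "L")

SILICON_NPA_SPACING = 108
SILICON_ARR = ("G", "S", "G", "R")

AROMATIC = set("FWY")
ACIDIC = set("DE")
BASIC = set("KRH")


@dataclass(frozen=True)
class SdpProfile:
    """Degenerate residue-set pattern for one substrate class."""

    substrate: str
    allowed: Tuple[FrozenSet[str], ...]

    def __post_init__(self) -> None:
        if len(self.allowed) != 9:
            raise ValueError("an SDP profile has exactly 9 positions")
        if any(not s for s in self.allowed):
            raise ValueError("every SDP position set must be nonempty")


def load_profiles(fixture: Optional[Fixture] = None) -> Dict[str, SdpProfile]:
    """Parse the typical-transporter profile table into SdpProfile objects."""
    fixture = fixture or load_fixture("table4_profiles")
    profiles = {}
    for _, row in fixture.table.iterrows():
        allowed = tuple(
            frozenset(row[f"sdp{i}"].split("/")) for i in range(1, 10)
        )
        profiles[row["substrate"]] = SdpProfile(row["substrate"], allowed)
    return profiles


def match_sdp(vector: Sequence[str], profile: SdpProfile) -> List[int]:
    """1-based SDP positions where ``vector`` violates ``profile``.

    A missing residue (the '-' marker) always mismatches: absence of an
    extractable residue is treated conservatively, never as a wildcard.
    """
    if len(vector) != 9:
        raise ValueError(f"SDP vector must have 9 entries, got {len(vector)}")
    return [
        i + 1
        for i, (res, allowed) in enumerate(zip(vector, profile.allowed))
        if res == MISSING or res not in allowed
    ]


@dataclass
class SpecificityReport:
    mismatches: Dict[str, List[int]]
    max_mismatch: int = 0

    @property
    def substrates(self) -> set:
        return {
            s for s, mm in self.mismatches.items() if len(mm) <= self.max_mismatch
        }

    @property
    def near_misses(self) -> Dict[str, List[int]]:
        """Non-matching substrates within two positions of the profile."""
        return {
            s: mm
            for s, mm in self.mismatches.items()
            if self.max_mismatch < len(mm) <= 2
        }


def predict_substrates(
    sdp_vectors: Mapping[str, Sequence[str]],
    profiles: Mapping[str, SdpProfile],
    max_mismatch: int = 0,
) -> SpecificityReport:
    """Match a protein's per-class SDP vectors against the typical profiles.

    A substrate is predicted when its vector has at most ``max_mismatch``
    violations (default 0: single-position deviations are "novel" patterns,
    reported as near-misses rather than matches).
    """
    mismatches = {
        substrate: match_sdp(sdp_vectors[substrate], profile)
        for substrate, profile in profiles.items()
        if substrate in sdp_vectors
    }
    return SpecificityReport(mismatches=mismatches, max_mismatch=max_mismatch)


# ---------------------------------------------------------------------------
# Froger discrimination


def froger_classify(positions: Sequence[str]) -> Tuple[str, List[str]]:
    """Classify the five Froger positions against AqpZ/GlpF exemplars.

    Each position is called by exemplar identity first; positions matching
    neither exemplar fall back to the generic aquaglyceroporin chemistry
    (aromatic P1, acidic P2, basic P3, proline P4, nonaromatic P5).  The
    overall call is aquaporin-like (all AqpZ), aquaglyceroporin-like
    (all GlpF), or mixed.
    """
    if len(positions) != 5:
        raise ValueError(f"expected 5 Froger positions, got {len(positions)}")
    glpf_rules = (
        lambda r: r in AROMATIC,
        lambda r: r in ACIDIC,
        lambda r: r in BASIC,
        lambda r: r == "P",
        lambda r: r not in AROMATIC and r != MISSING,
    )
    calls = []
    for i, res in enumerate(positions):
        if res == AQPZ_FROGER[i]:
            calls.append("aqpz-like")
        elif res == GLPF_FROGER[i]:
            calls.append("glpf-like")
        elif res != MISSING and glpf_rules[i](res):
            calls.append("glpf-like")
        else:
            calls.append("other")
    if all(c == "aqpz-like" for c in calls):
        overall = "aquaporin-like"
    elif all(c == "glpf-like" for c in calls):
        overall = "aquaglyceroporin-like"
    else:
        overall = "mixed"
    return overall, calls


def arR_water_call(arr: Sequence[str]) -> str:
    """'high' water permeability iff the filter is exactly F-H-T-R."""
    if len(arr) != 4:
        raise ValueError(f"expected 4 ar/R residues, got {len(arr)}")
    return "high" if tuple(arr) == ("F", "H", "T", "R") else "unknown"


def silicon_feature(
    npa_spacing: Optional[int], arr: Sequence[str]
) -> Tuple[bool, str]:
    """Silicon-transporter spacing rule with an ar/R corroboration note."""
    if npa_spacing is not None and npa_spacing < 0:
        raise ValueError("npa_spacing must be >= 0")
    flag = npa_spacing == SILICON_NPA_SPACING
    if not flag:
        note = ""
    elif tuple(arr) == SILICON_ARR:
        note = "supported by G-S-G-R ar/R"
    else:
        note = "ar/R filter atypical for silicon transporters"
    return flag, note
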