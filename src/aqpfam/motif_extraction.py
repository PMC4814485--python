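"""Structure-anchored residue extraction.

Each query protein is globally aligned to the annotated reference backbone
(:mod:`aqpfam.synthetic_reference`); the alignment induces a map from
annotated reference columns to query indices, from which the NPA motifs,
the ar/R selectivity filter (H2, H5, LE1, LE2), the five Froger positions,
and the per-substrate SDP vectors are read off.  Transmembrane segments
come from a Kyte-Doolittle hydropathy scan and molecular weight / pI from
standard physicochemical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .alignment import align_global, validate_protein
from .io_formats import MISSING
from .synthetic_reference import DEFAULT_TOPOLOGY, SDP_CLASSES, ReferenceTopology

MIN_QUERY_LENGTH = 100
NPA_SEARCH_WINDOW = 10


class NotMipLikeError(ValueError):
    """Query does not align to the reference above the relatedness floor."""


@dataclass
class ResidueAnnotation:
    npa_lb: Optional[str]
    npa_le: Optional[str]
    npa_spacing: Optional[int]
    arr: Tuple[str, str, str, str]
    froger: Tuple[str, str, str, str, str]
    sdp: Dict[str, Tuple[str, ...]] = field(default_factory=dict)


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    length: int
    mw_kda: float
    pi: float
    tm_segments: List[Tuple[int, int]]


# ---------------------------------------------------------------------------
# reference mapping


def map_to_reference(
    query: str,
    topology: ReferenceTopology = DEFAULT_TOPOLOGY,
    *,
    min_score: float = 50.0,
) -> Dict[int, Optional[int]]:
    """Map annotated reference columns onto query indices.

    Returns ``{reference column -> query index or None}`` for every position
    0..len(reference)-1, built from the global alignment.  A query shorter
    than 100 residues or scoring below ``min_score`` is rejected as not
    MIP-like.
    """
    query = validate_protein(query, what="query")
    if len(query) < MIN_QUERY_LENGTH:
        raise NotMipLikeError(
            f"query length {len(query)} below minimum {MIN_QUERY_LENGTH}"
        )
    aln = align_global(topology.reference_seq, query)
    if aln.score < min_score:
        raise NotMipLikeError(
            f"alignment score {aln.score:.1f} below relatedness floor {min_score}"
        )
    ref_row, qry_row = str(aln[0]), str(aln[1])
    posmap: Dict[int, Optional[int]] = {}
    ri = qi = 0
    for col in range(len(ref_row)):
        r, q = ref_row[col], qry_row[col]
        if r != "-" and q != "-":
            posmap[ri] = qi
        elif r != "-":
            posmap[ri] = None
        if r != "-":
            ri += 1
        if q != "-":
            qi += 1
    return posmap


# ---------------------------------------------------------------------------
# extraction


def _triplet_at(query: str, idx: Optional[int]) -> Optional[str]:
    if idx is None or idx + 3 > len(query):
        return None
    t = query[idx : idx + 3]
    return t if t[1] == "P" else None


def _find_npa(query: str, posmap, motif_col: int) -> Optional[int]:
    """Query start index of the x-P-x triplet nearest ``motif_col``.

    The mapped column is tried first; otherwise a +/-10 column window is
    scanned, preferring N/S at the first position and then proximity, since
    divergent subfamilies carry first- and third-position motif variants.
    """
    candidates = []
    for off in range(-NPA_SEARCH_WINDOW, NPA_SEARCH_WINDOW + 1):
        idx = posmap.get(motif_col + off)
        t = _triplet_at(query, idx)
        if t is not None:
            preference = 0 if t[0] in "NS" else 1
            candidates.append((preference, abs(off), idx))
    if not candidates:
        return None
    return min(candidates)[2]


def extract_npa(
    query: str,
    posmap: Dict[int, Optional[int]],
    topology: ReferenceTopology = DEFAULT_TOPOLOGY,
) -> Tuple[Optional[str], Optional[str], Optional[int]]:
    """Extract the loop-B and loop-E NPA-motif triplets and their spacing.

    Spacing counts residues strictly between the two motif-start (Asn)
    positions; 108 is the hallmark of silicon-permeable channels.
    """
    lb_idx = _find_npa(query, posmap, topology.npa_lb_col)
    le_idx = _find_npa(query, posmap, topology.npa_le_col)
    npa_lb = query[lb_idx : lb_idx + 3] if lb_idx is not None else None
    npa_le = query[le_idx : le_idx + 3] if le_idx is not None else None
    spacing = None
    if lb_idx is not None and le_idx is not None:
        spacing = le_idx - lb_idx - 1
    return npa_lb, npa_le, spacing


def extract_positions(
    query: str,
    posmap: Dict[int, Optional[int]],
    position_set: Sequence[int],
) -> Tuple[str, ...]:
    """Query residues at the given reference columns; '-' where gapped."""
    out = []
    for col in position_set:
        idx = posmap.get(col)
        out.append(query[idx] if idx is not None else MISSING)
    return tuple(out)


# ---------------------------------------------------------------------------
# hydropathy TM finder (simple substitute for a dedicated topology predictor)

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def hydropathy_tm_segments(
    query: str,
    *,
    window: int = 19,
    threshold: float = 1.6,
    merge_gap: int = 3,
) -> List[Tuple[int, int]]:
    """Predict transmembrane segments from windowed mean hydropathy.

    Maximal runs of window centers whose mean Kyte-Doolittle hydropathy
    exceeds ``threshold``; runs separated by fewer than ``merge_gap``
    centers are merged.  Segments are 0-based inclusive residue spans
    covering the full window extent.
    """
    query = validate_protein(query, what="query")
    if len(query) < window:
        return []
    half = window // 2
    values = [KYTE_DOOLITTLE[a] for a in query]
    acc = [0.0]
    for v in values:
        acc.append(acc[-1] + v)
    centers = [
        i
        for i in range(half, len(query) - half)
        if (acc[i + half + 1] - acc[i - half]) / window > threshold
    ]
    if not centers:
        return []
    runs: List[List[int]] = [[centers[0], centers[0]]]
    for c in centers[1:]:
        if c - runs[-1][1] < merge_gap:
            runs[-1][1] = c
        else:
            runs.append([c, c])
    return [
        (max(0, lo - half), min(len(query) - 1, hi + half)) for lo, hi in runs
    ]


# ---------------------------------------------------------------------------
# physicochemical properties

#: EMBOSS pKa set used for the isoelectric point.
PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (EMBOSS pKa set)."""
    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10 ** (pka - ph))

    charge = pos(PKA_POSITIVE["nterm"]) + neg(PKA_NEGATIVE["cterm"])
    for aa in seq:
        if aa in PKA_POSITIVE:
            charge += pos(PKA_POSITIVE[aa])
        elif aa in PKA_NEGATIVE:
            charge += neg(PKA_NEGATIVE[aa])
    return charge


def physicochem(seq: str, *, tol: float = 1e-4) -> Tuple[float, float]:
    """Average molecular weight (Da) and isoelectric point of a protein.

    The pI is the unique root of the monotone-decreasing net-charge curve,
    found by bisection on pH 0..14 to ``tol``.
    """
    seq = validate_protein(seq)
    mw = ProteinAnalysis(seq).molecular_weight()
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo) <= 0 or net_charge(seq, hi) >= 0:
        # charge curve is strictly decreasing with these pKa tables,
        # so the bracket always holds; guard anyway
        raise ValueError("net charge does not bracket a root on pH 0..14")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return mw, 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# one-call annotation


def annotate_protein(
    protein_id: str,
    query: str,
    topology: ReferenceTopology = DEFAULT_TOPOLOGY,
    *,
    min_score: float = 50.0,
) -> Tuple[ProteinRecord, ResidueAnnotation]:
    """Full structural annotation of one protein."""
    query = validate_protein(query, what=protein_id)
    posmap = map_to_reference(query, topology, min_score=min_score)
    npa_lb, npa_le, spacing = extract_npa(query, posmap, topology)
    annotation = ResidueAnnotation(
        npa_lb=npa_lb,
        npa_le=npa_le,
        npa_spacing=spacing,
        arr=extract_positions(query, posmap, topology.arr_cols),
        froger=extract_positions(query, posmap, topology.froger_cols),
        sdp={
            cls: extract_positions(query, posmap, topology.sdp_cols[cls])
            for cls in SDP_CLASSES
        },
    )
    mw, pi = physicochem(query)
    record = ProteinRecord(
        id=protein_id,
        sequence=query,
        length=len(query),
        mw_kda=mw / 1000.0,
        pi=pi,
        tm_segments=hydropathy_tm_segments(query),
    )
    return record, annotation
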