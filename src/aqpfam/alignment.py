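"""Shared protein/nucleotide alignment helpers.

All pairwise alignment in the package goes through Biopython's
:class:`Bio.Align.PairwiseAligner` in global mode with BLOSUM62 scoring and
affine gap penalties (open 10, extend 0.5), the standard setting for
intra-family membrane-protein comparison.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

GAP_OPEN = 10.0
GAP_EXTEND = 0.5


@lru_cache(maxsize=None)
def blosum62():
    return substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=None)
def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="global",
        substitution_matrix=blosum62(),
        open_gap_score=-GAP_OPEN,
        extend_gap_score=-GAP_EXTEND,
    )
    return aligner


@lru_cache(maxsize=None)
def nucleotide_aligner() -> Align.PairwiseAligner:
    # match/mismatch in the BLASTN spirit; gaps costed so that short indels
    # stay localized, which is what the frameshift caller needs.
    return Align.PairwiseAligner(
        mode="global",
        match_score=5.0,
        mismatch_score=-4.0,
        open_gap_score=-10.0,
        extend_gap_score=-1.0,
    )


def validate_protein(seq: str, *, what: str = "sequence") -> str:
    """Upper-case ``seq`` and reject empty or non-standard residues."""
    if not seq:
        raise ValueError(f"empty {what}")
    seq = seq.upper()
    bad = set(seq) - set(STANDARD_AA)
    if bad:
        raise ValueError(
            f"non-standard residue(s) {sorted(bad)} in {what}"
        )
    return seq


def align_global(a: str, b: str):
    """Best global alignment of two protein sequences."""
    return protein_aligner().align(a, b)[0]


def _trimmed_columns(aln):
    """Column range of ``aln`` with terminal-gap columns removed."""
    sa, sb = str(aln[0]), str(aln[1])
    start, end = 0, len(sa)
    while start < end and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    return sa, sb, start, end


def percent_similarity(a: str, b: str) -> float:
    """Percent similarity between two proteins.

    Defined as 100 x (aligned residue pairs with a positive BLOSUM62 score)
    / (global alignment length excluding terminal gaps).  This is the
    package's reproducible proxy for Clustal-style percent similarity.
    """
    a = validate_protein(a)
    b = validate_protein(b)
    aln = align_global(a, b)
    sa, sb, start, end = _trimmed_columns(aln)
    if end <= start:
        return 0.0
    matrix = blosum62()
    positive = sum(
        1
        for i in range(start, end)
        if sa[i] != "-" and sb[i] != "-" and matrix[sa[i], sb[i]] > 0
    )
    return 100.0 * positive / (end - start)


def alignment_score(a: str, b: str) -> float:
    return align_global(a, b).score
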