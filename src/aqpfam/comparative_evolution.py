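"""Cross-species comparison: best-hit ortholog tables, duplicate-pair
typing, species-by-subgroup count matrices, and ancestral family-size
bookkeeping.

Duplicate typing follows the classic genomic reading: a tandem pair sits
on one scaffold, same orientation, with no family member in between
(foot-to-head order); a dispersed pair sits on different chromosomes;
anything else is a whole-genome-duplication candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .alignment import alignment_score, percent_similarity
from .gene_inventory import GeneRecord
from .io_formats import Fixture, load_fixture


# ---------------------------------------------------------------------------
# best-hit orthologs


def best_hit_table(
    queries: Mapping[str, str],
    panels: Mapping[str, Mapping[str, str]],
    *,
    min_similarity: float = 25.0,
    min_score: float = 100.0,
) -> pd.DataFrame:
    """Best similarity hit per query and target species.

    ``panels`` maps species -> {target id -> sequence}.  A hit must clear
    both the similarity floor and an absolute score floor (the
    database-free surrogate for a stringent E-value cutoff).  Ties break
    deterministically by target id, so panel order never matters.
    """
    rows = []
    for qid, qseq in queries.items():
        for species, targets in panels.items():
            best: Optional[Tuple[float, str]] = None
            for tid in sorted(targets):
                sim = percent_similarity(qseq, targets[tid])
                if sim < min_similarity:
                    continue
                if alignment_score(qseq, targets[tid]) < min_score:
                    continue
                if best is None or sim > best[0] + 1e-9:
                    best = (sim, tid)
            if best is not None:
                rows.append(
                    {"query": qid, "species": species,
                     "best_hit": best[1], "similarity": best[0]}
                )
    return pd.DataFrame(rows, columns=["query", "species", "best_hit", "similarity"])


# ---------------------------------------------------------------------------
# duplicate pairs


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    pair_type: str  # tandem | dispersed | wgd-candidate
    evidence: str


def _span(rec: GeneRecord) -> Tuple[int, int]:
    if rec.identified_span is None:
        raise ValueError(f"{rec.name}: no coordinates for duplicate typing")
    s, e = rec.identified_span
    return (min(s, e), max(s, e))


def classify_duplicate_pair(
    a: GeneRecord, b: GeneRecord, inventory: Sequence[GeneRecord]
) -> DuplicatePair:
    """Type one duplicate pair as tandem, dispersed, or WGD candidate."""
    if a.name == b.name:
        raise ValueError("a duplicate pair needs two distinct genes")
    names = {r.name for r in inventory}
    if a.name not in names or b.name not in names:
        raise ValueError("both genes must be in the inventory")
    # symmetric: order by coordinate-independent gene name
    first, second = sorted((a, b), key=lambda r: r.name)
    if first.scaffold == second.scaffold and first.strand == second.strand:
        lo_a, hi_a = _span(first)
        lo_b, hi_b = _span(second)
        window = (min(lo_a, lo_b), max(hi_a, hi_b))
        intervening = [
            r.name
            for r in inventory
            if r.name not in (first.name, second.name)
            and r.scaffold == first.scaffold
            and r.identified_span is not None
            and window[0] < _span(r)[0] < window[1]
        ]
        if not intervening:
            return DuplicatePair(
                first.name, second.name, "tandem",
                f"same scaffold {first.scaffold}, strand {first.strand}, adjacent",
            )
    if first.chromosome != second.chromosome:
        return DuplicatePair(
            first.name, second.name, "dispersed",
            f"different chromosomes {first.chromosome}/{second.chromosome}",
        )
    return DuplicatePair(
        first.name, second.name, "wgd-candidate",
        f"same chromosome {first.chromosome}, non-adjacent",
    )


# ---------------------------------------------------------------------------
# subgroup count matrix


def subgroup_count_matrix(
    assignments: Iterable[Tuple[str, str]]
) -> pd.DataFrame:
    """Species x subgroup integer counts from (species, subgroup) pairs."""
    rows = list(assignments)
    if not rows:
        return pd.DataFrame(dtype=int)
    df = pd.DataFrame(rows, columns=["species", "subgroup"])
    matrix = (
        df.groupby(["species", "subgroup"]).size().unstack(fill_value=0)
    )
    matrix.columns.name = None
    matrix.index.name = "species"
    return matrix


def subfamily_totals(matrix: pd.DataFrame, species: str) -> Dict[str, int]:
    """Collapse a subgroup count row to subfamily totals."""
    out: Dict[str, int] = {}
    for subgroup, count in matrix.loc[species].items():
        subfamily = "".join(ch for ch in subgroup if not ch.isdigit())
        out[subfamily] = out.get(subfamily, 0) + int(count)
    return out


# ---------------------------------------------------------------------------
# ancestral reconstruction


def ancestral_counts(
    matrix: pd.DataFrame,
    pair_annotations: Iterable[Tuple[str, str]] = (),
    outgroup: str = "poplar",
    pseudogenes: Iterable[Tuple[str, str]] = (),
) -> Tuple[Dict[str, int], int]:
    """Estimate per-subgroup ancestral counts with an outgroup vote.

    A subgroup is ancestral when the outgroup carries it or at least two
    ingroup species do.  Its count is the maximum ingroup count after
    collapsing annotated lineage-specific duplicate pairs (each pair counts
    once, whatever its type) and excluding pseudogenes.
    """
    if outgroup not in matrix.index:
        raise ValueError(f"outgroup {outgroup!r} not in the count matrix")
    ingroup = [s for s in matrix.index if s != outgroup]
    pair_discount: Dict[Tuple[str, str], int] = {}
    for sp, sg in pair_annotations:
        pair_discount[(sp, sg)] = pair_discount.get((sp, sg), 0) + 1
    pseudo_discount: Dict[Tuple[str, str], int] = {}
    for sp, sg in pseudogenes:
        pseudo_discount[(sp, sg)] = pseudo_discount.get((sp, sg), 0) + 1

    counts: Dict[str, int] = {}
    for subgroup in matrix.columns:
        present_out = int(matrix.loc[outgroup, subgroup]) > 0
        n_ingroup_present = sum(
            1 for sp in ingroup if int(matrix.loc[sp, subgroup]) > 0
        )
        if not (present_out or n_ingroup_present >= 2):
            continue
        best = 0
        for sp in ingroup:
            c = int(matrix.loc[sp, subgroup])
            c -= pair_discount.get((sp, subgroup), 0)
            c -= pseudo_discount.get((sp, subgroup), 0)
            best = max(best, c)
        if best > 0:
            counts[subgroup] = best
    return counts, sum(counts.values())


def load_ancestral_fixture(
    fixture: Optional[Fixture] = None,
) -> Tuple[Dict[str, int], int]:
    """The packaged per-subgroup ancestral Euphorbiaceae counts."""
    fixture = fixture or load_fixture("ancestral_counts")
    counts = {
        row["subgroup"]: int(row["count"]) for _, row in fixture.table.iterrows()
    }
    return counts, sum(counts.values())
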