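"""Pairwise similarity, subfamily/subgroup assignment against a labelled
reference panel, neighbor-joining tree construction, and systematic-name
assignment.

Assignment is nearest-reference classification on percent similarity, the
operational stand-in for placing a query inside a reference phylogeny: a
query inherits the subfamily and subgroup of its most similar labelled
reference, with a similarity floor and an absolute alignment-score floor
guarding against non-MIP queries (random proteins reach 25-30% "similarity"
under any positive-pair definition, but their alignment scores stay near
zero while genuine family members score in the hundreds).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alignment import align_global, percent_similarity, validate_protein

DEFAULT_SIMILARITY_FLOOR = 25.0
DEFAULT_SCORE_FLOOR = 50.0


@dataclass(frozen=True)
class PanelReference:
    id: str
    seq: str
    subfamily: str
    subgroup: str


def load_panel(path) -> List[PanelReference]:
    """Read a labelled panel FASTA; headers carry key=value labels, e.g.
    ``>HbTIP2;1 subfamily=TIP subgroup=TIP2``."""
    from Bio import SeqIO

    entries = [
        (rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    return panel_from_fasta_descriptions(entries)


def panel_from_fasta_descriptions(
    entries: Sequence[Tuple[str, str]]
) -> List[PanelReference]:
    """Build a panel from (header, seq) pairs with key=value labels."""
    panel = []
    for header, seq in entries:
        tokens = header.split()
        rid = tokens[0]
        labels = dict(t.split("=", 1) for t in tokens[1:] if "=" in t)
        if "subfamily" not in labels or "subgroup" not in labels:
            raise ValueError(
                f"panel record {rid!r} lacks subfamily=/subgroup= labels"
            )
        panel.append(
            PanelReference(rid, seq.upper(), labels["subfamily"], labels["subgroup"])
        )
    return panel


@dataclass
class SubfamilyAssignment:
    query_id: str
    subfamily: Optional[str]
    subgroup: Optional[str]
    nearest_id: Optional[str]
    similarity: float
    margin: float

    @property
    def classified(self) -> bool:
        return self.subfamily is not None


def pairwise_similarity(a: str, b: str) -> float:
    """Percent similarity (positive-scoring aligned pairs / alignment
    length excluding terminal gaps) between two proteins."""
    return percent_similarity(a, b)


def similarity_matrix(records: Sequence[Tuple[str, str]]):
    """Symmetric percent-similarity matrix over labelled sequences."""
    import pandas as pd

    ids = [r[0] for r in records]
    n = len(ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s = pairwise_similarity(records[i][1], records[j][1])
            values[i, j] = values[j, i] = s
    return pd.DataFrame(values, index=ids, columns=ids)


def assign_subfamily(
    query_id: str,
    query_seq: str,
    panel: Sequence[PanelReference],
    *,
    similarity_floor: float = DEFAULT_SIMILARITY_FLOOR,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> SubfamilyAssignment:
    """Assign a query to the subfamily/subgroup of its nearest reference.

    Ties on best similarity are broken by a subgroup vote among the top-3
    references, then by lexicographic reference id.  Queries below either
    floor are returned unclassified.
    """
    query_seq = validate_protein(query_seq, what=query_id)
    if not panel:
        raise ValueError("empty reference panel")
    scored = []
    for ref in panel:
        aln_score = align_global(ref.seq, query_seq).score
        scored.append((pairwise_similarity(query_seq, ref.seq), aln_score, ref))
    scored.sort(key=lambda t: (-t[0], t[2].id))
    best_sim, best_score, best_ref = scored[0]

    ties = [t for t in scored if abs(t[0] - best_sim) < 1e-9]
    if len(ties) > 1:
        top3_groups = [t[2].subgroup for t in scored[:3]]
        votes = {g: top3_groups.count(g) for g in top3_groups}
        ties.sort(key=lambda t: (-votes.get(t[2].subgroup, 0), t[2].id))
        best_sim, best_score, best_ref = ties[0]

    other = [s for s, _, r in scored if r.subfamily != best_ref.subfamily]
    margin = best_sim - max(other) if other else best_sim
    if best_sim < similarity_floor or best_score < score_floor:
        return SubfamilyAssignment(query_id, None, None, None, best_sim, 0.0)
    return SubfamilyAssignment(
        query_id, best_ref.subfamily, best_ref.subgroup, best_ref.id,
        best_sim, max(margin, 0.0),
    )


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{c.newick()}:{bl:.17g}" for c, bl in self.children
        )
        return f"({inner})"


def build_nj_tree(ids: Sequence[str], d) -> str:
    """Neighbor-joining tree (Newick, unrooted) from a distance matrix.

    Standard Saitou-Nei agglomeration.  Negative branch lengths, which NJ
    can produce on non-additive input, are clamped to zero with the deficit
    moved onto the sister edge so that the path length through the joined
    pair is preserved.
    """
    d = np.asarray(d, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes = [_Node(label=i) for i in ids]
    dist = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i, j] for j in active if j != i) for i in active}
        best, pair = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if best is None or q < best - 1e-12:
                    best, pair = q, (i, j)
        i, j = pair
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # grow the matrix with the new cluster's distances
        dist = np.pad(dist, ((0, 1), (0, 1)))
        k = dist.shape[0] - 1
        for x in active:
            if x in (i, j):
                continue
            dist[k, x] = dist[x, k] = 0.5 * (
                dist[i, x] + dist[j, x] - dist[i, j]
            )
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    root = _Node(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return root.newick() + ";"


def distance_from_similarity(sim_percent) -> np.ndarray:
    """d = 1 - similarity/100, the distance used for classification trees."""
    return 1.0 - np.asarray(sim_percent, dtype=float) / 100.0


# ---------------------------------------------------------------------------
# systematic names


def _hint_index(hint: str) -> Tuple[int, str]:
    m = re.search(r";(\d+)$", hint)
    return (int(m.group(1)) if m else 10**9, hint)


def assign_systematic_names(
    assignments: Sequence[SubfamilyAssignment],
    ortholog_hints: Optional[Mapping[str, str]] = None,
    *,
    species_prefix: str = "",
) -> Dict[str, Optional[str]]:
    """Assign ``<subgroup>;<index>`` names within each subgroup.

    Queries with an ortholog hint are indexed first, in the order of the
    hint's own index (so a pair hinted at ``HbTIP2;1``/``HbTIP2;3`` becomes
    ``TIP2;1``/``TIP2;2``); the rest follow by decreasing similarity.
    Unclassified queries keep no systematic name.
    """
    ortholog_hints = ortholog_hints or {}
    names: Dict[str, Optional[str]] = {}
    by_group: Dict[str, List[SubfamilyAssignment]] = {}
    for a in assignments:
        if not a.classified:
            names[a.query_id] = None
            continue
        by_group.setdefault(a.subgroup, []).append(a)
    for subgroup, members in by_group.items():
        hinted = sorted(
            (a for a in members if a.query_id in ortholog_hints),
            key=lambda a: _hint_index(ortholog_hints[a.query_id]),
        )
        unhinted = sorted(
            (a for a in members if a.query_id not in ortholog_hints),
            key=lambda a: (-a.similarity, a.query_id),
        )
        for idx, a in enumerate(hinted + unhinted, 1):
            names[a.query_id] = f"{species_prefix}{subgroup};{idx}"
    return names
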