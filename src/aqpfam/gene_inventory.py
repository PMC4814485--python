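"""Gene-catalog curation: record arithmetic, family-level summaries, and
pseudogene flagging.

The catalog row layout follows genome-survey convention: coding length
(start to stop codon, introns excluded), gene length (start to stop codon,
introns included), a printed coordinate pair whose order encodes the
strand, EST/read expression evidence, and cross-species best-hit orthologs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .alignment import nucleotide_aligner
from .io_formats import MISSING, Fixture, load_fixture, parse_span

SUBFAMILIES = ("PIP", "TIP", "NIP", "SIP", "XIP")


def subfamily_from_name(name: str) -> Tuple[str, str]:
    """Split a systematic name like ``JcPIP2;4`` into (subfamily, subgroup)."""
    for sf in SUBFAMILIES:
        idx = name.find(sf)
        if idx >= 0:
            rest = name[idx + len(sf):]
            digits = ""
            for ch in rest:
                if ch.isdigit():
                    digits += ch
                else:
                    break
            return sf, sf + digits
    raise ValueError(f"cannot derive subfamily from name {name!r}")


@dataclass
class GeneRecord:
    """One curated catalog row."""

    name: str
    scaffold: str
    locus: Optional[str]
    chromosome: str
    strand: str
    cds_len: int
    gene_len: int
    identified_span: Optional[Tuple[int, int]]
    introns: List[int] = field(default_factory=list)
    utr5: Optional[int] = None
    utr3: Optional[int] = None
    est_hits: int = 0
    expressed_by_est: bool = False
    expressed_by_reads: bool = False
    splice_by_reads: bool = False
    splice_by_est: bool = False
    subfamily: str = ""
    subgroup: str = ""
    pseudogene: bool = False
    orthologs: Dict[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cds_len % 3 != 0:
            raise ValueError(f"{self.name}: cds_len not divisible by 3")
        if self.gene_len < self.cds_len:
            raise ValueError(f"{self.name}: gene_len < cds_len")
        if any(i <= 0 for i in self.introns):
            raise ValueError(f"{self.name}: intron lengths must be > 0")
        if self.est_hits < 0:
            raise ValueError(f"{self.name}: est_hits must be >= 0")
        if not self.subfamily:
            self.subfamily, self.subgroup = subfamily_from_name(self.name)

    @property
    def expressed(self) -> bool:
        return self.expressed_by_est or self.expressed_by_reads


def _cell(value: str) -> Optional[str]:
    return None if value == MISSING else value


def record_from_row(row) -> GeneRecord:
    """Build a :class:`GeneRecord` from one inventory-fixture row."""
    if row["identified_start"] != MISSING:
        strand, lo, hi = parse_span(row["identified_start"], row["identified_end"])
        span: Optional[Tuple[int, int]] = (int(row["identified_start"]),
                                           int(row["identified_end"]))
    elif row["predicted_start"] != MISSING:
        strand, _, _ = parse_span(row["predicted_start"], row["predicted_end"])
        span = None
    else:
        strand, span = "+", None
    introns = (
        [int(x) for x in row["introns"].split(",")]
        if row["introns"] != MISSING
        else []
    )
    est = 0 if row["est_hits"] == MISSING else int(row["est_hits"])
    return GeneRecord(
        name=row["name"],
        scaffold=row["scaffold"],
        locus=_cell(row["locus"]),
        chromosome=row["chromosome"],
        strand=strand,
        cds_len=int(row["cds_len"]),
        gene_len=int(row["gene_len"]),
        identified_span=span,
        introns=introns,
        utr5=None if row["utr5"] == MISSING else int(row["utr5"]),
        utr3=None if row["utr3"] == MISSING else int(row["utr3"]),
        est_hits=est,
        expressed_by_est=est > 0,
        expressed_by_reads=row["expressed"] == "Yes",
        splice_by_est=row["splice_est"] == "Yes",
        splice_by_reads=row["splice_read"] == "Yes",
        orthologs={
            sp: _cell(row[f"{sp}_ortholog"]) for sp in ("at", "pt", "rc", "hb")
        },
    )


def load_inventory(fixture: Optional[Fixture] = None) -> List[GeneRecord]:
    fixture = fixture or load_fixture("table2_inventory")
    return [record_from_row(row) for _, row in fixture.table.iterrows()]


# ---------------------------------------------------------------------------
# gene-model arithmetic


def protein_length_from_cds(cds_len: int) -> int:
    """Residues encoded by a CDS of ``cds_len`` bp (stop codon excluded)."""
    if cds_len < 6:
        raise ValueError("CDS must cover at least start and stop codons")
    if cds_len % 3 != 0:
        raise ValueError(
            f"CDS length {cds_len} not divisible by 3 (frameshift?)"
        )
    return cds_len // 3 - 1


@dataclass
class SpanReport:
    gene_span: int
    transcript_span: Optional[int]
    genomic_span: Optional[int]
    inconsistencies: List[str] = field(default_factory=list)


def reconstruct_spans(rec: GeneRecord) -> SpanReport:
    """Recompute the span arithmetic of one record and flag conflicts.

    gene span = CDS + introns; transcript span adds the UTRs; genomic span
    comes from the printed coordinate pair.  Inconsistencies are reported,
    never raised: printed catalogs do contain them, and surfacing the
    conflict is the point.
    """
    gene_span = rec.cds_len + sum(rec.introns)
    transcript_span = None
    if rec.utr5 is not None and rec.utr3 is not None:
        transcript_span = gene_span + rec.utr5 + rec.utr3
    genomic_span = None
    if rec.identified_span is not None:
        s, e = rec.identified_span
        genomic_span = abs(e - s) + 1
    flags = []
    if rec.introns and gene_span != rec.gene_len:
        flags.append(
            f"gene_span {gene_span} != recorded gene length {rec.gene_len}"
        )
    expected = transcript_span if transcript_span is not None else rec.gene_len
    if genomic_span is not None and genomic_span != expected:
        flags.append(
            f"genomic span {genomic_span} != expected transcript extent {expected}"
        )
    return SpanReport(gene_span, transcript_span, genomic_span, flags)


# ---------------------------------------------------------------------------
# family summary


@dataclass
class FamilySummary:
    n_genes: int
    n_scaffolds: int
    multi_gene_scaffolds: List[str]
    per_chromosome_counts: Dict[str, int]
    n_chromosomes_multi: int
    orf_min: Optional[int]
    orf_max: Optional[int]
    gene_min: Optional[int]
    gene_max: Optional[int]
    n_est_supported: int
    max_est: Optional[Tuple[str, int]]
    n_splice_read: int
    n_splice_est: int
    subfamily_counts: Dict[str, int]
    intron_mean: Optional[float]
    intron_min: Optional[int]
    intron_max: Optional[int]


def _intron_lengths(rec: GeneRecord) -> List[int]:
    # Catalog rows rarely list per-intron lengths; fall back to the total
    # intronic span as a single unresolved pseudo-intron.
    if rec.introns:
        return list(rec.introns)
    total = rec.gene_len - rec.cds_len
    return [total] if total > 0 else []


def family_summary(records: Sequence[GeneRecord]) -> FamilySummary:
    scaffold_counts = Counter(r.scaffold for r in records)
    chrom_counts = Counter(r.chromosome for r in records)
    est_supported = [r for r in records if r.est_hits > 0]
    introns = [l for r in records for l in _intron_lengths(r)]
    max_est = None
    if est_supported:
        best = max(est_supported, key=lambda r: r.est_hits)
        max_est = (best.name, best.est_hits)
    return FamilySummary(
        n_genes=len(records),
        n_scaffolds=len(scaffold_counts),
        multi_gene_scaffolds=sorted(
            s for s, c in scaffold_counts.items() if c > 1
        ),
        per_chromosome_counts=dict(chrom_counts),
        n_chromosomes_multi=sum(1 for c in chrom_counts.values() if c > 1),
        orf_min=min((r.cds_len for r in records), default=None),
        orf_max=max((r.cds_len for r in records), default=None),
        gene_min=min((r.gene_len for r in records), default=None),
        gene_max=max((r.gene_len for r in records), default=None),
        n_est_supported=len(est_supported),
        max_est=max_est,
        n_splice_read=sum(1 for r in records if r.splice_by_reads),
        n_splice_est=sum(1 for r in records if r.splice_by_est),
        subfamily_counts=dict(Counter(r.subfamily for r in records)),
        intron_mean=(sum(introns) / len(introns)) if introns else None,
        intron_min=min(introns, default=None),
        intron_max=max(introns, default=None),
    )


# ---------------------------------------------------------------------------
# pseudogene flagging


@dataclass
class PseudogeneCall:
    flag: bool
    evidence: List[str]


def flag_pseudogene(
    cds_seq: str,
    consensus_cds: str,
    *,
    expressed: bool = False,
    min_score: float = 0.0,
) -> PseudogeneCall:
    """Flag a coding sequence as a pseudogene candidate.

    Evidence is an ORF disruption relative to an intact same-subgroup
    consensus: a frameshifting indel (gap length not a multiple of 3 in the
    pairwise alignment) or a premature stop codon.  The flag itself also
    requires the absence of expression evidence — a disrupted but expressed
    locus is reported with evidence yet not flagged.
    """
    cds_seq = cds_seq.upper()
    consensus_cds = consensus_cds.upper()
    if not cds_seq or not consensus_cds:
        raise ValueError("empty CDS")
    aln = nucleotide_aligner().align(consensus_cds, cds_seq)[0]
    if aln.score < min_score:
        raise ValueError(
            f"sequences not alignable (score {aln.score} below floor {min_score})"
        )
    ref, qry = str(aln[0]), str(aln[1])

    evidence: List[str] = []
    i = 0
    ref_pos = 0  # 1-based consensus coordinate of the last consumed base
    while i < len(ref):
        if ref[i] == "-" or qry[i] == "-":
            j = i
            in_query = ref[i] == "-"
            while j < len(ref) and (ref[j] == "-" if in_query else qry[j] == "-"):
                j += 1
            run = j - i
            # terminal overhangs are length differences, not frameshifts
            interior = i > 0 and j < len(ref)
            if interior and run % 3 != 0:
                kind = "insertion" if in_query else "frameshift"
                evidence.append(f"{kind}@{ref_pos + 1}")
            if not in_query:
                ref_pos += run
            i = j
        else:
            ref_pos += 1
            i += 1

    n_codons = len(cds_seq) // 3
    protein = str(Seq(cds_seq[: n_codons * 3]).translate())
    stop = protein.find("*")
    if 0 <= stop < n_codons - 1:
        evidence.append(f"premature_stop@{stop * 3 + 1}")

    return PseudogeneCall(flag=bool(evidence) and not expressed, evidence=evidence)
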