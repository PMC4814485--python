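"""Seeded generators for AQP-like families with planted ground truth.

The generator emulates the statistical structure of a plant MIP family:

* a family of 32 genes split 9/9/8/4/2 over the PIP/TIP/NIP/SIP/XIP
  subfamilies by default, each subfamily subdivided into the subgroups
  observed in Euphorbiaceae genomes;
* per-subgroup diagnostic residues (ar/R filter, NPA triplets, Froger
  positions, SDP vectors) planted at the reference-mapped columns, taken
  from the published subgroup-typical patterns;
* subfamily-typical exon-intron structures (PIPs three introns, TIPs two,
  NIPs four, SIP1s none, ...);
* tissue expression with PIP-dominant lognormal FPKM ground truth and
  Poisson fragment counts.

Subfamily and subgroup base sequences derive from the synthetic reference
backbone with conserved transmembrane cores and variable loops; they are
fixed library constants (independent of the user seed) so that they can
double as the labelled classification panel.  Everything else is a pure
function of (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import STANDARD_AA
from .family_classifier import PanelReference
from .io_formats import FastaRecord, GeneModel
from .synthetic_reference import DEFAULT_TOPOLOGY, SDP_CLASSES, ReferenceTopology

# divergence of the fixed subfamily/subgroup backbones; transmembrane cores
# are conserved relative to loops, as in real MIP families
SUBFAMILY_TM_RATE = 0.10
SUBFAMILY_LOOP_RATE = 0.30
SUBGROUP_LOOP_RATE = 0.05

#: median true FPKM per subfamily (PIP-dominant expression hierarchy)
SUBFAMILY_FPKM_MEDIAN = {
    "PIP": 60.0, "TIP": 40.0, "SIP": 1.2, "NIP": 0.8, "XIP": 0.02,
}
FPKM_SIGMA = 1.0

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"


@dataclass(frozen=True)
class SubgroupTemplate:
    subgroup: str
    subfamily: str
    arr: Tuple[str, str, str, str]
    npa_lb: str
    npa_le: str
    froger: Tuple[str, str, str, str, str]
    sdp: Mapping[str, Optional[Tuple[str, ...]]]
    intron_ranges: Tuple[Tuple[int, int], ...]


def _t(s: str) -> Tuple[str, ...]:
    return tuple(s.split("-"))


_PIP_INTRONS = ((83, 481), (90, 1751), (87, 487))
_TIP_INTRONS = ((75, 302), (77, 372))
_NIP_INTRONS = ((70, 1063), (72, 957), (79, 980), (88, 262))

TEMPLATES: Dict[str, SubgroupTemplate] = {
    t.subgroup: t
    for t in [
        SubgroupTemplate(
            "PIP1", "PIP", _t("F-H-T-R"), "NPA", "NPA", _t("E-S-A-F-W"),
            {"urea": _t("H-P-F-F-L-P-G-G-N"),
             "boric acid": _t("T-I-H-P-E-L-L-T-P"),
             "CO2": _t("I-M-C-A-I-D-W-D-W"),
             "H2O2": _t("A-G-V-F-I-H-F-V-P")},
            _PIP_INTRONS,
        ),
        SubgroupTemplate(
            "PIP2", "PIP", _t("F-H-T-R"), "NPA", "NPA", _t("Q-S-A-F-W"),
            {"urea": _t("H-P-F-F-L-P-G-G-N"),
             "CO2": _t("I-M-C-A-V-D-W-D-W"),
             "H2O2": _t("A-G-V-F-I-Q-F-V-P")},
            _PIP_INTRONS,
        ),
        SubgroupTemplate(
            "TIP1", "TIP", _t("H-I-A-V"), "NPA", "NPA", _t("T-S-A-Y-W"),
            {"urea": _t("H-P-F-F-L-A-G-S-N"),
             "H2O2": _t("S-A-L-A-I-H-Y-V-P")},
            _TIP_INTRONS,
        ),
        SubgroupTemplate(
            "TIP2", "TIP", _t("H-I-G-R"), "NPA", "NPA", _t("T-S-A-Y-W"),
            {"urea": _t("H-P-F-A-L-P-G-S-N")},
            _TIP_INTRONS,
        ),
        SubgroupTemplate(
            "TIP3", "TIP", _t("H-I-A-R"), "NPA", "NPA", _t("T-A-A-Y-W"),
            {"H2O2": _t("S-A-L-V-I-H-Y-V-P")},
            _TIP_INTRONS,
        ),
        SubgroupTemplate(
            "TIP4", "TIP", _t("H-I-A-R"), "NPA", "NPA", _t("T-S-A-Y-W"),
            {"urea": _t("H-P-L-L-L-A-G-S-N")},
            _TIP_INTRONS,
        ),
        SubgroupTemplate(
            "TIP5", "TIP", _t("N-V-G-S"), "NPA", "NPA", _t("I-A-A-Y-W"),
            {"urea": _t("H-P-F-A-L-P-G-S-N"),
             "H2O2": _t("S-A-L-A-I-Q-Y-V-P")},
            _TIP_INTRONS,
        ),
        SubgroupTemplate(
            "NIP1", "NIP", _t("W-V-A-R"), "NPA", "NPA", _t("F-S-A-Y-L"),
            {"NH3": _t("F-K-F-T-A-D-L-E-T"),
             "urea": _t("H-P-L-A-L-P-G-S-N")},
            _NIP_INTRONS,
        ),
        SubgroupTemplate(
            "NIP2", "NIP", _t("G-S-G-R"), "NPA", "NPA", _t("L-T-A-Y-I"),
            {"boric acid": _t("V-V-H-P-E-I-I-A-P"),
             "H2O2": _t("A-A-L-L-V-I-Y-V-P"),
             "silicic acid": _t("G-F-V-H-G-N-R-T-K"),
             "urea": _t("H-P-T-A-M-P-G-S-N")},
            _NIP_INTRONS,
        ),
        SubgroupTemplate(
            "NIP3", "NIP", _t("W-V-A-R"), "NPA", "NPA", _t("F-S-A-F-L"),
            {"urea": _t("H-P-I-A-L-P-G-S-N")},
            _NIP_INTRONS,
        ),
        SubgroupTemplate(
            "NIP4", "NIP", _t("W-V-A-R"), "NPA", "NPA", _t("F-S-A-Y-I"),
            {"H2O2": _t("S-A-L-L-V-L-Y-A-P"),
             "urea": _t("H-P-I-A-L-P-G-S-N")},
            _NIP_INTRONS,
        ),
        SubgroupTemplate(
            "NIP5", "NIP", _t("S-I-A-R"), "NPA", "NPV", _t("F-T-A-Y-L"),
            {"boric acid": _t("T-I-H-P-E-L-L-A-P"),
             "H2O2": _t("S-A-L-V-V-I-Y-V-P"),
             "urea": _t("H-P-I-A-L-P-G-S-N")},
            _NIP_INTRONS[:3],
        ),
        SubgroupTemplate(
            "NIP6", "NIP", _t("S-I-A-R"), "NPS", "NPV", _t("L-T-A-Y-L"),
            {"boric acid": _t("T-I-H-P-E-L-L-A-P"),
             "urea": _t("H-P-I-A-L-P-G-S-N")},
            _NIP_INTRONS,
        ),
        SubgroupTemplate(
            "NIP7", "NIP", _t("A-V-G-R"), "NPA", "NPA", _t("Y-S-A-Y-I"),
            {},
            _NIP_INTRONS,
        ),
        SubgroupTemplate(
            "SIP1", "SIP", _t("V-L-P-N"), "NPT", "NPA", _t("I-A-A-Y-W"),
            {},
            (),
        ),
        SubgroupTemplate(
            "SIP2", "SIP", _t("S-L-G-S"), "NPL", "NPA", _t("F-V-A-Y-W"),
            {},
            ((100, 3000), (100, 5879)),
        ),
        SubgroupTemplate(
            "XIP1", "XIP", _t("I-I-V-R"), "SPI", "NPA", _t("M-C-A-F-W"),
            {},
            ((100, 1000),),
        ),
        SubgroupTemplate(
            "XIP2", "XIP", _t("I-T-V-R"), "NPV", "NPA", _t("L-C-A-F-W"),
            {},
            ((100, 1000), (100, 1000)),
        ),
    ]
}

#: default family composition: 9 PIPs, 9 TIPs, 8 NIPs, 4 SIPs, 2 XIPs
DEFAULT_LAYOUT: Dict[str, Tuple[str, ...]] = {
    "PIP": ("PIP1",) * 4 + ("PIP2",) * 5,
    "TIP": ("TIP1",) * 4 + ("TIP2",) * 2 + ("TIP3", "TIP4", "TIP5"),
    "NIP": ("NIP1", "NIP2", "NIP3", "NIP3", "NIP4", "NIP5", "NIP6", "NIP7"),
    "SIP": ("SIP1", "SIP1", "SIP1", "SIP2"),
    "XIP": ("XIP1", "XIP2"),
}


@dataclass
class SimConfig:
    n_per_subfamily: Mapping[str, int] = field(
        default_factory=lambda: {"PIP": 9, "TIP": 9, "NIP": 8, "SIP": 4, "XIP": 2}
    )
    substitution_rate: float = 0.1
    indel_rate: float = 0.0
    tissues: Tuple[str, ...] = ("root", "leaf", "seed")
    mean_library_size: int = 30_000_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if any(n < 0 for n in self.n_per_subfamily.values()):
            raise ValueError("n_per_subfamily values must be >= 0")
        if self.mean_library_size <= 0:
            raise ValueError("mean_library_size must be positive")


@dataclass
class SimulatedFamily:
    proteins: List[FastaRecord]
    cds: List[FastaRecord]
    models: List[GeneModel]
    truth: pd.DataFrame
    topology: ReferenceTopology


# ---------------------------------------------------------------------------
# sequence machinery


def _stable_seed(tag: str) -> int:
    return zlib.crc32(tag.encode())


def _substitute(aa: str, rng: np.random.Generator) -> str:
    choices = STANDARD_AA.replace(aa, "")
    return choices[rng.integers(len(choices))]


def mutate_copy(
    seq: str,
    rng: np.random.Generator,
    substitution_rate: float,
    indel_rate: float = 0.0,
    protected: FrozenSet[int] = frozenset(),
) -> Tuple[str, List[Tuple[str, int, str, str]]]:
    """Point-mutate (and optionally indel) a protein; return an edit log.

    Positions refer to the input sequence (0-based).  Protected positions
    are never touched, which keeps planted diagnostic residues intact.
    """
    edits: List[Tuple[str, int, str, str]] = []
    residues = list(seq)
    for i, aa in enumerate(residues):
        if i in protected:
            continue
        if rng.random() < substitution_rate:
            new = _substitute(aa, rng)
            residues[i] = new
            edits.append(("sub", i, aa, new))
    if indel_rate > 0:
        out: List[str] = []
        for i, aa in enumerate(residues):
            if i not in protected and rng.random() < indel_rate:
                if rng.random() < 0.5:
                    edits.append(("del", i, aa, ""))
                    continue
                ins = STANDARD_AA[rng.integers(len(STANDARD_AA))]
                edits.append(("ins", i, "", ins))
                out.append(ins)
            out.append(aa)
        residues = out
    return "".join(residues), edits


def _tm_columns(topology: ReferenceTopology) -> FrozenSet[int]:
    return frozenset(
        c for lo, hi in topology.tm_spans for c in range(lo, hi)
    )


#: residues flanking each annotated column that stay conserved; diagnostic
#: residues sit inside conserved motif contexts (the NPA box, the ar/R
#: constriction), which is also what keeps them alignable in real families
MOTIF_FLANK = 2


def protected_columns(
    topology: ReferenceTopology, flank: int = MOTIF_FLANK
) -> FrozenSet[int]:
    n = len(topology.reference_seq)
    out = set()
    for col in topology.annotated_columns():
        out.update(
            c for c in range(col - flank, col + flank + 1) if 0 <= c < n
        )
    return frozenset(out)


def _plant(seq: List[str], template: SubgroupTemplate,
           topology: ReferenceTopology) -> None:
    for col, res in zip(topology.arr_cols, template.arr):
        seq[col] = res
    for col, res in zip(topology.froger_cols, template.froger):
        seq[col] = res
    for off, res in enumerate(template.npa_lb):
        seq[topology.npa_lb_col + off] = res
    for off, res in enumerate(template.npa_le):
        seq[topology.npa_le_col + off] = res
    for cls, vector in template.sdp.items():
        if vector is None:
            continue
        for col, res in zip(topology.sdp_cols[cls], vector):
            seq[col] = res


def subgroup_base_sequence(
    subgroup: str, topology: ReferenceTopology = DEFAULT_TOPOLOGY
) -> str:
    """Fixed diverged backbone of one subgroup with its planted residues."""
    template = TEMPLATES[subgroup]
    conserved = protected_columns(topology)
    tm = _tm_columns(topology)
    seq = list(topology.reference_seq)

    sf_rng = np.random.default_rng(_stable_seed("subfamily:" + template.subfamily))
    for i in range(len(seq)):
        if i in conserved:
            continue
        rate = SUBFAMILY_TM_RATE if i in tm else SUBFAMILY_LOOP_RATE
        if sf_rng.random() < rate:
            seq[i] = _substitute(seq[i], sf_rng)

    sg_rng = np.random.default_rng(_stable_seed("subgroup:" + subgroup))
    for i in range(len(seq)):
        if i in conserved or i in tm:
            continue
        if sg_rng.random() < SUBGROUP_LOOP_RATE:
            seq[i] = _substitute(seq[i], sg_rng)

    _plant(seq, template, topology)
    return "".join(seq)


def reference_panel(
    topology: ReferenceTopology = DEFAULT_TOPOLOGY,
) -> List[PanelReference]:
    """Labelled subgroup base sequences, usable as a classification panel."""
    return [
        PanelReference(
            id=f"Ref{sg}",
            seq=subgroup_base_sequence(sg, topology),
            subfamily=TEMPLATES[sg].subfamily,
            subgroup=sg,
        )
        for sg in TEMPLATES
    ]


# ---------------------------------------------------------------------------
# family generation


def back_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein) + _STOP


def _allocate_subgroups(cfg: SimConfig) -> List[str]:
    chosen = []
    for subfamily in ("PIP", "TIP", "NIP", "SIP", "XIP"):
        n = cfg.n_per_subfamily.get(subfamily, 0)
        layout = DEFAULT_LAYOUT[subfamily]
        chosen.extend(layout[i % len(layout)] for i in range(n))
    return chosen


def _gene_model(
    gene_id: str,
    scaffold: str,
    strand: str,
    offset: int,
    cds_len: int,
    intron_lengths: Sequence[int],
) -> GeneModel:
    n_exons = len(intron_lengths) + 1
    # exon nucleotide lengths: near-equal split of the CDS
    bounds = [round(cds_len * k / n_exons) for k in range(n_exons + 1)]
    exons, pos = [], offset
    for k in range(n_exons):
        exon_len = bounds[k + 1] - bounds[k]
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len
        if k < len(intron_lengths):
            pos += intron_lengths[k]
    return GeneModel(
        gene_id=gene_id, scaffold=scaffold, strand=strand,
        exons=exons, cds=list(exons),
    )


def simulate_family(
    cfg: SimConfig, topology: ReferenceTopology = DEFAULT_TOPOLOGY
) -> SimulatedFamily:
    """Generate a family (proteins, CDS, gene models, truth) from ``cfg``."""
    rng = np.random.default_rng(cfg.rng_seed)
    conserved = protected_columns(topology)
    subgroups = _allocate_subgroups(cfg)

    counters: Dict[str, int] = {}
    proteins, cds_records, models, rows = [], [], [], []
    scaffold_no = 0
    pending_tandem: Optional[Tuple[str, int, str]] = None  # scaffold, offset, strand
    nip3_seen = 0

    for subgroup in subgroups:
        template = TEMPLATES[subgroup]
        counters[subgroup] = counters.get(subgroup, 0) + 1
        gene = f"Sim{subgroup};{counters[subgroup]}"

        base = subgroup_base_sequence(subgroup, topology)
        protein, _ = mutate_copy(
            base, rng, cfg.substitution_rate, cfg.indel_rate, protected=conserved
        )
        cds = back_translate(protein)

        intron_lengths = [
            int(rng.integers(lo, hi + 1)) for lo, hi in template.intron_ranges
        ]

        pair_id = "-"
        if subgroup == "SIP1" and counters[subgroup] in (2, 3):
            # adjacent same-strand neighbors on one scaffold: a tandem pair
            pair_id = "SIP1_tandem"
            if counters[subgroup] == 2:
                scaffold_no += 1
                scaffold = f"sim_scaffold{scaffold_no:03d}"
                offset, strand = 1001, "+"
            else:
                scaffold, prev_end, strand = pending_tandem
                offset = prev_end + 501
        else:
            scaffold_no += 1
            scaffold = f"sim_scaffold{scaffold_no:03d}"
            offset = 1001
            strand = "+" if scaffold_no % 2 else "-"
        if subgroup == "NIP3":
            nip3_seen += 1
            if nip3_seen <= 2:
                pair_id = "NIP3_dispersed"

        model = _gene_model(
            gene, scaffold, strand, offset, len(cds), intron_lengths
        )
        if subgroup == "SIP1" and counters[subgroup] == 2:
            pending_tandem = (scaffold, model.end, strand)

        chromosome = f"LG{(scaffold_no - 1) % 11 + 1}"
        fpkm_true = {
            tissue: float(
                np.exp(
                    np.log(SUBFAMILY_FPKM_MEDIAN[template.subfamily])
                    + FPKM_SIGMA * rng.standard_normal()
                )
            )
            for tissue in cfg.tissues
        }

        posmap = {c: c for c in range(len(base))}  # planted truth is positional
        row = {
            "gene": gene,
            "subfamily": template.subfamily,
            "subgroup": subgroup,
            "scaffold": scaffold,
            "chromosome": chromosome,
            "strand": strand,
            "cds_len": len(cds),
            "n_introns": len(intron_lengths),
            # transcription order: minus-strand introns run downstream first
            "introns": ",".join(
                map(str,
                    intron_lengths[::-1] if strand == "-" else intron_lengths)
            ) or "-",
            "arr": "".join(template.arr),
            "npa_lb": template.npa_lb,
            "npa_le": template.npa_le,
            "npa_spacing": topology.npa_spacing,
            "froger": "".join(template.froger),
            "pair_id": pair_id,
        }
        for cls in SDP_CLASSES:
            row[f"sdp_{cls}"] = "".join(
                base[c] for c in topology.sdp_cols[cls]
            )
        for tissue in cfg.tissues:
            row[f"fpkm_{tissue}"] = fpkm_true[tissue]
        rows.append(row)
        proteins.append(FastaRecord(gene, protein))
        cds_records.append(FastaRecord(gene, cds))
        models.append(model)

    truth = pd.DataFrame(rows)
    return SimulatedFamily(
        proteins=proteins, cds=cds_records, models=models,
        truth=truth, topology=topology,
    )


# ---------------------------------------------------------------------------
# count simulation


def simulate_counts(truth: pd.DataFrame, cfg: SimConfig):
    """Poisson fragment counts around the truth table's FPKM ground truth."""
    from .expression_profiles import CountTable

    rng = np.random.default_rng(cfg.rng_seed + 1)
    tissues = list(cfg.tissues)
    genes = list(truth["gene"])
    eff_len = pd.Series(truth["cds_len"].astype(int).values, index=genes)
    total = cfg.mean_library_size
    counts = pd.DataFrame(0, index=genes, columns=tissues, dtype=int)
    for tissue in tissues:
        mean = (
            truth[f"fpkm_{tissue}"].astype(float).values
            * eff_len.values
            * total
            / 1e9
        )
        counts[tissue] = rng.poisson(mean)
    totals = pd.Series(total, index=tissues)
    return CountTable(counts=counts, eff_len=eff_len, totals=totals)
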