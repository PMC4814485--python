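"""Readers and writers for the on-disk formats, packaged table fixtures,
and the pipeline configuration.

Conventions
-----------
* FASTA: parsed with Biopython, identifiers taken up to the first
  whitespace, residues upper-cased.  Duplicate identifiers are an error.
* GFF3: 1-based inclusive coordinates.  Gene models are normalized to
  ``(scaffold, strand, start<=end)`` with an explicit ``+``/``-`` strand
  flag; descending coordinate pairs in legacy catalog tables are read as
  minus-strand.
* TSV dialect: tab-separated, ``#``-prefixed header line, UTF-8, ``-`` for
  missing values (the dash convention of printed gene-catalog tables).
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, NamedTuple, Sequence, Tuple

from urllib.parse import quote, unquote

import gffutils
import pandas as pd
from Bio import SeqIO

MISSING = "-"

# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Tunable thresholds of the pipeline.

    ``similarity_screen_threshold`` is an absolute alignment-score floor used
    as the database-free surrogate for an E-value cutoff when screening
    candidates; ``ortholog_min_score`` plays the same role for best-hit
    ortholog calls; ``est_identity_min`` is the minimum identity fraction for
    an EST to count as support; ``expressed_min_fragments`` is the smallest
    mapped-fragment count called expressed (2, i.e. "more than one").
    """

    similarity_screen_threshold: float = 50.0
    ortholog_min_score: float = 100.0
    est_identity_min: float = 0.98
    expressed_min_fragments: int = 2
    log2_pseudocount: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.est_identity_min <= 1.0:
            raise ValueError("est_identity_min must be in (0, 1]")
        if self.expressed_min_fragments < 1:
            raise ValueError("expressed_min_fragments must be >= 1")
        if self.log2_pseudocount <= 0:
            raise ValueError("log2_pseudocount must be positive")


def read_config(path: str | os.PathLike) -> PipelineConfig:
    """Parse a ``key: value`` text file into a :class:`PipelineConfig`."""
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    casts = {
        "similarity_screen_threshold": float,
        "ortholog_min_score": float,
        "est_identity_min": float,
        "expressed_min_fragments": int,
        "log2_pseudocount": float,
        "rng_seed": int,
    }
    kwargs = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"line {lineno}: expected 'key: value'")
            key, _, value = line.partition(":")
            key = key.strip()
            if key not in fields:
                raise ValueError(
                    f"line {lineno}: unknown config key {key!r} "
                    f"(known: {sorted(fields)})"
                )
            kwargs[key] = casts[key](value.strip())
    return PipelineConfig(**kwargs)


def write_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name}: {getattr(config, f.name)}\n")


# ---------------------------------------------------------------------------
# FASTA


class FastaRecord(NamedTuple):
    id: str
    seq: str


def read_fasta(path: str | os.PathLike) -> List[FastaRecord]:
    """Read a FASTA file into ordered ``(id, seq)`` records.

    Residues are upper-cased.  Structural problems are reported with the
    offending line number; duplicate identifiers are listed explicitly.
    """
    header_line = None
    with open(path, encoding="utf-8") as fh:
        saw_data = False
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header_line is not None and not saw_data:
                    raise ValueError(
                        f"line {header_line}: record has an empty sequence"
                    )
                if len(line) == 1:
                    raise ValueError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                saw_data = False
            else:
                if header_line is None:
                    raise ValueError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                saw_data = True
        if header_line is not None and not saw_data:
            raise ValueError(f"line {header_line}: record has an empty sequence")

    records = [
        FastaRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(os.fspath(path), "fasta")
    ]
    seen: Dict[str, int] = {}
    dups = []
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate FASTA identifier(s): {dups}")
    return records


def write_fasta(
    records: Sequence[Tuple[str, str]], path: str | os.PathLike, width: int = 60
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


@dataclass
class GeneModel:
    """One gene with ordered exon and CDS parts (1-based inclusive)."""

    gene_id: str
    scaffold: str
    strand: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for lo, hi in self.exons + self.cds:
            if lo > hi:
                raise ValueError(f"{self.gene_id}: part with start > end")
        prev_end = None
        for lo, hi in self.cds:
            if prev_end is not None and lo <= prev_end:
                raise ValueError(
                    f"{self.gene_id}: overlapping CDS parts within one isoform"
                )
            prev_end = hi

    @property
    def start(self) -> int:
        return min(lo for lo, _ in self.exons)

    @property
    def end(self) -> int:
        return max(hi for _, hi in self.exons)

    @property
    def intron_lengths(self) -> List[int]:
        """Gaps between consecutive exons, in transcription order."""
        gaps = [
            self.exons[i + 1][0] - self.exons[i][1] - 1
            for i in range(len(self.exons) - 1)
        ]
        return gaps[::-1] if self.strand == "-" else gaps

    @property
    def cds_length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.cds)


def read_gff3(path: str | os.PathLike) -> List[GeneModel]:
    """Read gene models (gene -> mRNA -> exon/CDS) from a GFF3 file."""
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons, cds = [], []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons.extend(
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            )
            cds.extend(
                (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
            )
        models.append(
            GeneModel(
                gene_id=unquote(gene.id),
                scaffold=gene.seqid,
                strand=gene.strand,
                exons=exons or [(gene.start, gene.end)],
                cds=cds,
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        # ';' and friends are reserved in column 9 and must be %-escaped
        gid = quote(m.gene_id, safe="")
        attrs = f"ID={gid}"
        lines.append(
            "\t".join(
                [m.scaffold, "aqpfam", "gene", str(m.start), str(m.end), ".",
                 m.strand, ".", attrs]
            )
        )
        mrna_id = f"{gid}.t1"
        lines.append(
            "\t".join(
                [m.scaffold, "aqpfam", "mRNA", str(m.start), str(m.end), ".",
                 m.strand, ".", f"ID={mrna_id};Parent={gid}"]
            )
        )
        for lo, hi in m.exons:
            lines.append(
                "\t".join(
                    [m.scaffold, "aqpfam", "exon", str(lo), str(hi), ".",
                     m.strand, ".", f"Parent={mrna_id}"]
                )
            )
        for lo, hi in m.cds:
            lines.append(
                "\t".join(
                    [m.scaffold, "aqpfam", "CDS", str(lo), str(hi), ".",
                     m.strand, "0", f"Parent={mrna_id}"]
                )
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV dialect


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV with a '#'-prefixed header; all cells kept as strings."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: first line must be a '#'-prefixed header")
        columns = header[1:].split("\t")
        df = pd.read_csv(
            fh, sep="\t", names=columns, dtype=str, na_filter=False
        )
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df.copy()
    out = out.fillna(MISSING)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(map(str, out.columns)) + "\n")
        for _, row in out.iterrows():
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures


@dataclass(frozen=True)
class Fixture:
    name: str
    table: pd.DataFrame


FIXTURE_NAMES = (
    "table2_inventory",
    "table3_residues",
    "table4_profiles",
    "table4_observed",
    "ancestral_counts",
    "table1_family_sizes",
)


def _fixture_path(name: str):
    return resources.files("aqpfam.fixtures").joinpath(f"{name}.tsv")


def load_fixture(name: str) -> Fixture:
    """Load one packaged catalog table by name."""
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}"
        )
    ref = _fixture_path(name)
    with resources.as_file(ref) as p:
        table = read_tsv(p)
    return Fixture(name=name, table=table)


def fixture_sha256(name: str) -> str:
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}"
        )
    data = _fixture_path(name).read_bytes()
    return hashlib.sha256(data).hexdigest()


def parse_span(start: str | int, end: str | int) -> Tuple[str, int, int]:
    """Normalize a printed coordinate pair to (strand, min, max).

    Catalog tables encode the strand by coordinate order: a descending pair
    is a minus-strand gene.
    """
    s, e = int(start), int(end)
    if s <= e:
        return "+", s, e
    return "-", e, s
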