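"""Synthetic structural reference backbone for residue mapping.

Real MIP residue extraction is anchored on a structure-resolved plasma
membrane aquaporin.  No such experimentally determined sequence ships with
this package; instead this module constructs a SYNTHETIC reference protein
with the canonical MIP topology — six transmembrane helices (TM1-TM6), five
connecting loops (LA-LE), two NPA half-helix motifs in loops B and E, the
aromatic/arginine (ar/R) selectivity filter (H2, H5, LE1, LE2), the five
Froger positions (P1-P5), and nine specificity-determining positions (SDPs)
per non-aqua substrate class.  The backbone is a fixed artificial sequence,
not a transcription of any real protein; every annotated column is defined
by construction, which is exactly what planted-truth testing needs.

Layout (residue counts): N-tail 20, TM 6x21, loops A 10 / B 16 / C 20 /
D 10 / E 24, C-tail 20 — 246 residues in total.  The two NPA motif starts
sit 109 columns apart, i.e. 108 residues strictly between them, the spacing
reported for silicon-permeable NIP2-type channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

#: Substrate classes with published SDP profiles, in fixed package order.
SDP_CLASSES: Tuple[str, ...] = (
    "NH3",
    "boric acid",
    "CO2",
    "H2O2",
    "silicic acid",
    "urea",
)

_SEGMENTS: Tuple[Tuple[str, str], ...] = (
    ("nterm", "MSKEEVVSGAQSRDYHDPPP"),
    ("tm1", "AGLWSFVAEFIATLLFVFAGV"),
    ("loopA", "GSTQNPDKSG"),
    ("tm2", "LAVTIAGLVYGLFAIAVGHIS"),
    ("loopB", "SDKASSGLGAEQVGLM"),
    ("tm3", "GVLYWVAQLLGSTAAGLLLKF"),
    ("loopC", "VTDNGQRSEIAGTYESGDLK"),
    ("tm4", "AVIGEIIGTFVLVYTVFSATD"),
    ("loopD", "GKRNARDSHV"),
    ("tm5", "PVLAIGLSVALGHLLAIDYTG"),
    ("loopE", "CGINSARSFGSAVMYNKDKAWDDH"),
    ("tm6", "AIFWVVMIGLLGAAGAIGLNV"),
    ("cterm", "SLRSAEHDGQEMSGTKDYAN"),
)


def _segment_starts() -> Dict[str, int]:
    starts, pos = {}, 0
    for name, seq in _SEGMENTS:
        starts[name] = pos
        pos += len(seq)
    return starts


@dataclass(frozen=True)
class ReferenceTopology:
    """Annotated alignment columns of the reference backbone.

    All columns are 0-based indices into ``reference_seq``.  ``sdp_cols``
    maps each substrate class to its own nine columns; the classes use
    disjoint column sets so a protein carries one independent 9-residue
    vector per class, mirroring how SDP tables are organized.
    """

    reference_seq: str
    tm_spans: Tuple[Tuple[int, int], ...]
    npa_lb_col: int
    npa_le_col: int
    arr_cols: Tuple[int, int, int, int]  # H2, H5, LE1, LE2
    froger_cols: Tuple[int, int, int, int, int]
    sdp_cols: Mapping[str, Tuple[int, ...]] = field(default_factory=dict)

    @property
    def npa_spacing(self) -> int:
        """Residues strictly between the two NPA motif starts."""
        return self.npa_le_col - self.npa_lb_col - 1

    def annotated_columns(self) -> Tuple[int, ...]:
        cols = set()
        cols.update(range(self.npa_lb_col, self.npa_lb_col + 3))
        cols.update(range(self.npa_le_col, self.npa_le_col + 3))
        cols.update(self.arr_cols)
        cols.update(self.froger_cols)
        for nine in self.sdp_cols.values():
            cols.update(nine)
        return tuple(sorted(cols))

    def validate(self) -> None:
        n = len(self.reference_seq)
        cols = []
        cols.extend(self.arr_cols)
        cols.extend(self.froger_cols)
        cols.extend([self.npa_lb_col, self.npa_le_col])
        for nine in self.sdp_cols.values():
            if len(nine) != 9:
                raise ValueError("each substrate class needs 9 SDP columns")
            cols.extend(nine)
        if len(cols) != len(set(cols)):
            raise ValueError("annotated columns must be distinct")
        if not all(0 <= c < n for c in cols):
            raise ValueError("annotated column outside reference length")
        if not self.npa_lb_col < self.npa_le_col:
            raise ValueError("loop-B NPA must precede loop-E NPA")


def build_reference_topology() -> ReferenceTopology:
    starts = _segment_starts()
    backbone = list("".join(seq for _, seq in _SEGMENTS))

    npa_lb = starts["loopB"] + 4
    npa_le = starts["loopE"] + 4
    h2 = starts["tm2"] + 15
    h5 = starts["tm5"] + 12
    le1 = starts["loopE"] + 8
    le2 = starts["loopE"] + 11
    froger = (
        starts["loopC"] + 6,
        starts["loopE"] + 14,
        starts["loopE"] + 18,
        starts["tm6"] + 2,
        starts["tm6"] + 3,
    )

    # Canonical residues of the backbone: a PIP2-like water channel.
    plants = {
        h2: "F", h5: "H", le1: "T", le2: "R",
        froger[0]: "Q", froger[1]: "S", froger[2]: "A",
        froger[3]: "F", froger[4]: "W",
    }
    for off, res in enumerate("NPA"):
        plants[npa_lb + off] = res
        plants[npa_le + off] = res

    used = set(plants)
    tm_spans = tuple(
        (starts[name], starts[name] + len(seq))
        for name, seq in _SEGMENTS
        if name.startswith("tm")
    )
    loop_regions = [
        (starts[name], starts[name] + len(seq))
        for name, seq in _SEGMENTS
        if not name.startswith("tm")
    ]
    pool = [
        c
        for lo, hi in loop_regions
        for c in range(lo, hi)
        if c not in used
    ]
    # Interleave so each class's nine columns are spread along the protein.
    sdp_cols = {
        cls: tuple(pool[k + 6 * j] for j in range(9))
        for k, cls in enumerate(SDP_CLASSES)
    }

    for col, res in plants.items():
        backbone[col] = res

    topo = ReferenceTopology(
        reference_seq="".join(backbone),
        tm_spans=tm_spans,
        npa_lb_col=npa_lb,
        npa_le_col=npa_le,
        arr_cols=(h2, h5, le1, le2),
        froger_cols=froger,
        sdp_cols=sdp_cols,
    )
    topo.validate()
    return topo


DEFAULT_TOPOLOGY = build_reference_topology()
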