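# Methods

This note documents the models, conventions and numerical choices behind
`aqpfam`, in the order the pipeline runs.

## Gene-inventory model

A catalog row records, per gene: scaffold and locus identifiers, a printed
coordinate pair whose order encodes the strand (descending = minus strand),
the chromosome (linkage-group) label, coding length (start to stop codon,
introns excluded) and gene length (start to stop codon, introns included),
EST hit counts, read-based expression and alternative-splicing evidence,
and cross-species best-hit orthologs. Missing values use the dash
convention of printed tables.

**Span arithmetic.** "Gene length" means the start-to-stop-codon span
excluding UTRs; the transcript span adds the 5′ and 3′ UTRs. This is the
only reading under which a 720-bp CDS with 590- and 3167-bp introns gives a
4477-bp gene and, with 329/562-bp UTRs, a 5368-bp transcribed region equal
to the genomic extent of its coordinate pair. `reconstruct_spans` checks
these identities and *reports* conflicts rather than raising: printed
catalogs contain them (one SIP paralog's coordinate pair spans 908 bp
against a recorded intronless 729-bp gene), and surfacing the conflict is
the point of the checker.

**Intron statistics.** Where a row lacks per-intron lengths, the total
intronic span (gene − CDS) is treated as a single unresolved pseudo-intron;
summary statistics over such catalogs are therefore lower bounds on intron
counts, not estimates of intron-length distributions.

**Pseudogene calls** require both an ORF disruption (a frameshifting indel
— interior alignment gap with length not a multiple of 3 — or a premature
stop codon, located against an intact same-subgroup consensus) and the
absence of EST/read expression evidence. A disrupted but expressed locus is
reported with its evidence and not flagged. Nucleotide alignment uses
match/mismatch +5/−4 with gap open 10, extend 1; pairs scoring below 0 are
rejected as unalignable. Evidence positions are 1-based consensus
coordinates of the disruption.

## Reference topology and residue extraction

Extraction is anchored on a single annotated reference backbone
(`synthetic_reference.py`). Because no experimentally determined anchor
sequence ships with the package, the backbone is **synthetic**: a fixed
246-residue artificial protein with the canonical MIP layout (six 21-residue
TM helices, loops A–E, 20-residue termini) and explicitly planted canonical
residues — NPA in loops B and E (motif starts 109 columns apart, i.e. 108
residues strictly between the Asn positions), a PIP2-like F-H-T-R ar/R
filter (H2 in TM2, H5 in TM5, LE1/LE2 in loop E), Froger P1 in loop C,
P2/P3 in loop E, P4/P5 at the start of TM6, and nine SDP columns per
substrate class drawn from loop/terminal positions (classes use disjoint
column sets, mirroring the fact that each substrate's SDP set is its own
collection of alignment positions). All annotated columns are distinct and
validated at import.

**Mapping.** A query (≥100 residues) is globally aligned to the backbone
with BLOSUM62, gap open 10, extend 0.5 — the standard intra-family protein
setting. The alignment induces a column→query-index map; annotated columns
aligned to gaps extract the missing marker `-`. Queries scoring below an
absolute floor (default 50) are rejected as not MIP-like; see *Score floors*
below for why the floor is a score, not a similarity.

**NPA search.** The mapped motif column is tried first; failing that, a
±10-column window is scanned for any x-P-x triplet, preferring N/S at the
first position and then proximity. The literal triplet is reported (NPV,
NPS, NPT, NPL, SPI variants occur in divergent subfamilies). Spacing counts
residues strictly between the two motif-start positions; whether published
"distance between NPA motifs" figures count inclusively is not stated
anywhere we could verify, so this exclusive convention is a documented
choice, and the silicon rule (`spacing == 108`) is calibrated to it.

**TM scan.** Kyte–Doolittle hydropathy, window 19, threshold 1.6, runs of
above-threshold window centers merged when separated by fewer than 3
centers. This is a deliberately simple substitute for a dedicated topology
predictor: it recovers planted hydrophobic blocks exactly, but on noisy
sequences it merges or misses helices and its segment count is reported as
descriptive, never used as a filter.

**MW and pI.** Molecular weight is the standard average-mass residue sum
plus one water (via Biopython). The isoelectric point is computed in-house
by bisection (pH 0–14, tolerance 1e-4) on the Henderson–Hasselbalch net
charge with the EMBOSS pKa set (N-term 8.6, C-term 3.6, K 10.8, R 12.5,
H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1); Biopython's built-in pI hard-codes a
different (Bjellqvist) set. Published pI values computed with other pKa
tables agree only to roughly ±0.2 pH units, which is the tolerance any
comparison should use. The charge curve is strictly decreasing, so the root
is unique and the bracket always holds.

## Substrate specificity

Three evidence channels are kept separate, as they are argued in the
comparative AQP literature; no composite score is invented.

* **SDP profiles.** Each of six substrate classes (NH₃, boric acid, CO₂,
  H₂O₂, silicic acid, urea) has a degenerate 9-position profile
  (e.g. urea: H, P, F/I/L/T, A/C/F/L, L/M, A/G/P, G/S, G/S, N). A vector
  matches only with zero violations; missing residues always count as
  violations (conservative, never wildcards). Substrates violated at one or
  two positions are reported as near-misses — the literature calls such
  single-deviation patterns "novel SDPs", not matches.
* **Froger discrimination.** Each of P1–P5 is called against the AqpZ
  (A-S-A-F-W, water-selective) and GlpF (Y-D-K-P-L, glycerol permease)
  exemplars by identity first; positions matching neither fall back to the
  generic aquaglyceroporin chemistry (aromatic P1, acidic P2, basic P3,
  proline P4, nonaromatic P5) and otherwise call "other". All-AqpZ is
  aquaporin-like, all-GlpF aquaglyceroporin-like, anything else mixed.
* **ar/R and silicon.** Exactly F-H-T-R means a high-water-permeability
  call, anything else "unknown". NPA spacing of exactly 108 raises the
  silicon flag, with a corroboration note when the filter is G-S-G-R.

One documented conflict in the source tables: the prose describes a
NIP2-type vector A-A-L-L-V-I-Y-V-P as an "NH₃ SDP", but the table prints it
under the H₂O₂ section and it matches the H₂O₂ profile exactly (it violates
the NH₃ profile at several positions). The fixtures and tests follow the
table.

## Classification

**Percent similarity** is 100 × (aligned pairs with positive BLOSUM62
score) / (global alignment length excluding terminal gaps) — a reproducible
proxy for Clustal-style percent similarity, whose exact published
definition is unstated.

**Score floors.** Optimal global alignments of *random* 250-residue
proteins already reach 25–31% positive-pair similarity (measured over
seeded draws), so a 25% similarity floor alone cannot reject non-MIP
sequences. Their alignment *scores*, however, sit near zero (−26 to +3 in
the same draws) while genuine family members score in the hundreds.
Classification and ortholog search therefore require both the similarity
floor (25%) and an absolute score floor (50 for screening, 100 for
best-hit ortholog calls — the database-free surrogates for permissive and
stringent E-value cutoffs, since no database statistics are computed).

**Assignment** is nearest-reference: the query takes the subfamily and
subgroup of its most similar labelled panel reference; ties are broken by a
subgroup vote among the top three references, then lexicographic reference
id. The margin to the best reference of any other subfamily is reported.

**Neighbor joining** (Saitou–Nei) is implemented in-house on
d = 1 − similarity/100, with branch lengths emitted at full float
precision. Negative branch lengths — possible on non-additive input — are
clamped to zero with the deficit moved to the sister edge, preserving the
path length through the joined pair. On additive matrices the tree
reproduces all pairwise path lengths to < 1e-9 (verified against an
independent NJ implementation in the tests). The tree is classification
support, not a published-figure reproduction: maximum-likelihood
bootstrapping is a declared non-goal.

**Systematic names** are `<subgroup>;<index>`, indices given first to
queries carrying cross-species ortholog hints (ordered by the hint's own
index), then by decreasing similarity.

## Comparative analysis

A **tandem** pair shares one scaffold and orientation with no family member
between the two loci (the "same-direction neighbors, foot-to-head order"
criterion); a **dispersed** pair sits on different chromosomes; remaining
pairs are **WGD candidates**. The classification is symmetric in its
arguments.

**Ancestral counts.** No published reconstruction rule exists for the
ancestral family bookkeeping, so the implemented rule is a documented
default: a subgroup is ancestral when the outgroup carries it or at least
two ingroup species do, and its count is the maximum ingroup count after
collapsing annotated lineage-specific duplicate pairs (each pair counts
once) and excluding pseudogenes. The packaged per-subgroup ancestral list
(total 31) is shipped as data and summed as-is; the rule is exercised on
synthetic matrices only, so a guessed rule is never presented as the source
of the published total.

## Expression

FPKM = count × 10⁹ / (effective length × library total). The effective
length is the CDS length, because the counts are produced by mapping reads
to coding sequences; the library total is library-wide (whether published
pipelines used library-wide or family-restricted totals is unstated;
library-wide is the standard reading). A gene is expressed in a tissue when
more than one fragment maps (count ≥ 2). Subfamily shares are member
percentages of the subfamily FPKM total per tissue (undefined over a zero
total); fold ratios compare subfamily totals pairwise. Duplicate-pair
divergence is log₂((a + c)/(b + c)) per tissue with pseudocount c = 1
(the log₂ transform of published heatmaps states no constant; 1 is the
conventional choice), and a preference switch is flagged when the ratio
changes sign across tissues. Heatmap rows are ordered PIP, TIP, NIP, SIP,
XIP, then by name.

## Synthetic-data generator

The generator is the package's test bed; its defaults are the study
conditions the fixtures describe.

* **Composition**: 9 PIPs, 9 TIPs, 8 NIPs, 4 SIPs, 2 XIPs (32 genes), with
  the observed subgroup layout (4 PIP1 + 5 PIP2, 4 TIP1 + 2 TIP2 +
  TIP3/4/5, one NIP per subgroup with a NIP3 pair, 3 SIP1 + 1 SIP2,
  XIP1 + XIP2).
* **Sequences**: each subgroup has a fixed base sequence derived from the
  reference backbone — substitutions at 10% per site in TM cores and 30% in
  loops at the subfamily level plus 5% extra loop divergence at the
  subgroup level (conserved-core/variable-loop structure, as in real MIP
  families), with the subgroup's diagnostic residues (ar/R, NPA triplets,
  Froger, published SDP vectors) planted at the annotated columns. The
  annotated columns *and two flanking residues on each side* are never
  mutated: diagnostic residues sit inside conserved motif contexts (the NPA
  box, the ar/R constriction), and this flank is also what keeps the
  generative alignment recoverable — without it, one optimal alignment in a
  few hundred shifts a divergent TM window by a residue or two and
  extraction can no longer be exact even in the absence of indels. Bases
  are fixed library constants (seeded by name, independent of the user
  seed) so they double as the labelled classification panel. Per-gene noise
  applies the configured substitution rate (default 0.1) and indel rate
  (default 0) outside the protected columns.
* **Gene models**: CDS by most-frequent-codon back-translation (only
  lengths and frames matter downstream) with subfamily-typical intron
  templates — PIPs 3 introns (83–481, 90–1751, 87–487 bp), TIPs 2 (75–302,
  77–372), NIPs 4 (70–1063, 72–957, 79–980, 88–262; the NIP5 template 3),
  SIP1 none, SIP2 2, XIP1 1, XIP2 2. Two SIP1 genes are placed as adjacent
  same-strand neighbors on one scaffold (a tandem pair) and the NIP3 pair
  on different chromosomes (dispersed); truth rows carry the pair labels.
  Truth-table intron lists are in transcription order (reversed for
  minus-strand genes).
* **Expression**: true FPKM per gene and tissue is lognormal (σ = 1) around
  subfamily medians 60 (PIP), 40 (TIP), 1.2 (SIP), 0.8 (NIP), 0.02 (XIP) —
  the PIP-dominant hierarchy of real tissue profiles — over tissues root,
  leaf, seed with 3×10⁷ mapped fragments per library. Counts are Poisson
  with mean FPKM × CDS length × total / 10⁹.

**What the generator does not emulate**: phylogenetic site/rate
heterogeneity, codon usage, alternative splicing, UTRs, sequencing-error
structure, or between-library size variation. Passing the planted-truth
tests therefore shows the extraction, classification and quantification
machinery is correct under the stated noise model — not that the pipeline's
thresholds are optimal for any particular real genome.

## Problem sizes in the checks

The recovery properties are measured on 202-gene families (the default
composition scaled ×~6) for residue extraction, 100 replicate queries at
30% divergence for subfamily recovery, 10-taxon random additive matrices
for NJ exactness, and the default 32-gene family for FPKM estimator bias
(cells with expected count ≥ 50). These sizes give Monte-Carlo error well
inside the asserted bounds while the whole suite runs in seconds.

## Known limitations

* Extraction quality degrades with indel rate; the ±10-column NPA window
  and the global alignment absorb ~1 indel per 100 sites with ≥99.9%
  per-position accuracy, but heavily gapped families would need a profile
  (HMM) anchor instead of a single reference sequence.
* Percent similarity depends on the chosen optimal alignment when optima
  tie; values are deterministic for a given Biopython version but may shift
  at the last decimal across versions.
* The hydropathy TM finder is a heuristic stand-in; its counts should not
  be compared against dedicated topology predictors.
* The pI depends on the pKa set; cross-tool agreement is ±0.2 pH at best.
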