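# Methods

## The mining model

`cdrhmine` identifies *cloned disease-resistance gene homologs* (CDRHs):
genes in an annotated genome whose protein product is homologous, under
fixed acceptance rules, to at least one cloned and functionally confirmed
R gene. The workflow assumes:

* queries are complete protein sequences of cloned R genes;
* each target genome provides gene models (GFF3, 1-based inclusive
  coordinates), a proteome keyed by gene id, and a per-gene table of
  resistance-associated domain calls produced by an external annotation
  pipeline — domain prediction is out of scope by design;
* homology is assessed by local protein alignment; one accepted gene is
  one CDRH regardless of how many queries hit it (all source queries are
  kept on the record).

## Search and significance

The built-in engine performs exact Smith–Waterman alignment with affine
gaps under BLOSUM62 via Biopython's `PairwiseAligner`; a gap of length
*L* costs `gap_open + L·gap_extend` (defaults 11 and 1, the common
protein-BLAST setting). There is no seeding, masking or composition-based
adjustment: at desk scale every pair is aligned exactly, which removes a
whole class of heuristic artefacts from tests. The test suite pins the
scores to an independently written Gotoh dynamic program on random pairs.

Percent identity is `100·identities/columns` and percent similarity
`100·positives/columns`, a positive being an aligned pair with strictly
positive matrix score; columns include gap positions. Significance uses
the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the published gapped
BLOSUM62 constants (λ = 0.267, K = 0.041) as overridable defaults; the
E-value only gates filtering, so moderate inaccuracy in λ, K for other
matrices is immaterial. In proteome mode `n` is the total residue count
of the proteome; a cheap score-only pass skips the costly traceback for
pairs far above a BLAST-like reporting cutoff (E > 10), which cannot
change the set of accepted hits because the acceptance cutoff is 55
orders of magnitude stricter.

Genome mode six-frame-translates chromosomes (stop → `*`, N-containing
codon → `X`, trailing partial codon dropped) and maps alignment
coordinates back to base pairs with the strand recorded. Hits spanning a
stop codon score poorly across it; intron-split genes produce separate
per-exon hits (no HSP chaining — a stated non-goal).

## Acceptance rules

A hit is kept iff

* `evalue_min ≤ E ≤ evalue_max` (defaults 0 and 1e-45),
* percent similarity **strictly** greater than 70, and
* alignment length ≥ 148 aa.

Interpretation choices, all configurable:

* The historical phrasing of the E-value criterion ("outside E0 to
  E-45") is directionally ambiguous. The default keeps everything at
  least as significant as 1e-45 (`evalue_min = 0`): removing the *most*
  significant hits would discard the best homologs. The literal
  window reading is available by setting `evalue_min = 1e-45`.
* "Similarity" means positives-based percent similarity when the
  alignment provides positives; hits imported from 12-column tabular
  BLAST carry no positives column, so identity stands in and the hit is
  flagged (`similarity_is_identity`).
* The 148-aa rule derives from the smallest query protein (RPW8.1) and
  is applied to the alignment span, a property of the match, not to the
  subject protein length.
* Rejections carry the first failing rule in the order E-value,
  similarity, length, giving a deterministic audit table.

Accepted genome-mode hits resolve to the gene model with maximal bp
overlap on the hit's chromosome (ties → lowest start, then id); zero
overlap drops the hit with a warning. Multiple hits joining one query to
one gene keep the best E-value. A query never becomes a CDRH of itself:
the gene model named by the query's registry locus is excluded for that
query.

## RGA classification

Domain tokens {TIR, CC, NBS, LRR, RPW8, KINASE, LysM, TM} map to classes
through a fixed decision table, NBS branch first: the three canonical
full-length architectures (TNL, CNL, RNL — RPW8 with NBS counts as RNL
with or without LRR), the truncations (TN, CN, NL, bare NBS), any other
NBS-bearing combination → other-NLR. TIR without NBS is TX regardless of
other domains (including TIR+LRR). Kinases need a transmembrane segment
to be RLKs (LRR-, LysM-, else other-RLK); kinase-less membrane proteins
with LRR or LysM ectodomains are RLPs. Everything else — including
cytoplasmic kinases and bare CC or TM proteins, the classes of a few
registry entries (e.g. serine/threonine kinases) — is non-RGA, matching
their exclusion from the NLR/RLK/RLP superclasses. The table is total
and deterministic on all 256 token subsets and is pinned exhaustively in
the tests against an independently coded rule list.

RNL is treated as an NLR subclass throughout (it rolls up to NLR for
clustering and the class matrix).

## Homolog typing

Species identity alone decides ortholog vs paralog; sub-genome identity
is deliberately ignored (no homoeolog logic, a stated non-goal). The
tandem/segmented split uses the inter-interval gap
`max(0, max(starts) − min(ends))` — zero for overlapping genes — which is
symmetric in the two loci and invariant to gene length; the anchor-point
alternative (start-to-start) is not, which is why the gap was chosen.
The 5 Mb bound is inclusive: a gap of exactly 5,000,000 bp is tandem.

## Cluster detection

Per chromosome, genes sort by start (ties by id). Pass 1 sweeps each RGA
superclass independently with greedy left-to-right maximal windows: a
window absorbs the next same-superclass gene while the genomic span
(`max(end) − min(start)`) stays ≤ 200 kb and fewer than 8 members are
present; windows with ≥ 2 members are emitted and consumed. Pass 2
chains every unconsumed gene (non-RGAs included) under the same span
rule without a member cap and emits windows whose composition is mixed:
≥ 2 RGA superclasses, or ≥ 1 RGA with ≥ 1 non-RGA. Windows of only
non-RGA genes are discarded.

Design decisions, given that the cluster definition fixes no algorithm:

* "within a 200 kb region" is read as the cluster's genomic span, not
  pairwise gaps;
* the 8-member cap binds only homogeneous clusters, because the
  definition attaches it to "RGAs of the same class"; the cap closes a
  window, so nine co-located NLRs yield one 8-member cluster plus one
  unconsumed gene available to pass 2;
* the two passes are disjoint (a gene joins at most one cluster), with
  homogeneous detection taking precedence, so the two kinds can be
  reported as disjoint counts.

Every emitted cluster is re-validated against the span/size/composition
invariants at run time, and the greedy scan is equivalence-tested against
an independent window-enumeration oracle on random instances. One
plausible-sounding property is deliberately **not** asserted: enlarging
the span bound can *decrease* the number of clustered genes under any
left-to-right maximal-window rule (a larger first window can absorb a
gene whose former partner is then left alone), so monotonicity in
`span_bp` is not an invariant of this algorithm.

## The bundled registry

The 49-entry cloned-gene table ships with transcribed names, species,
RGA types, pathogen links, disease codes and accessions. Naming follows
the most consistent variant where sources disagree (canonical
`Bna_MAPk` with alias `Bna_MPK9`; `At_NRG1a/b` with `At_NGR1a/b`
aliases; `At_Rpw8.1/2` with upper-case aliases). Disease membership
follows the per-disease gene lists used for the published rollups, not
the pathogen column, where the two differ. Protein sequences are
**synthetic placeholders**: deterministic pseudo-random sequences seeded
from the gene id, with declared lengths (RPW8.1 fixed at 148 aa because
it anchors the length filter; other lengths are modest stand-ins of
148–380 aa chosen for fast desk-scale alignment). All registry-dependent
sequence results in the tests are therefore structural, not biological;
users with real sequences put them in the `protein_seq` column.

## Synthetic data: what it emulates and what it does not

The generator emulates multi-chromosome annotated genomes at the level
the pipeline consumes: gene models with realistic spacing, a proteome,
and domain annotations. Planted genes are substitution-mutated copies of
registry queries at controlled identity (no indels by default, so
realized identity equals the target within rounding and every plant sits
at a known distance from the 70% similarity rule); placements control
the tandem/segmented distances and cluster spans exactly, and planted
structures keep a 300 kb buffer from each other so planted clusters stay
maximal. Background genes carry random proteins and empty or single-token
non-RGA domain sets, so they can neither pass the homology filter nor
contaminate clusters.

The default study scenario (`default_study_config`) is two genomes
(B. napus–like A/C and B. rapa–like A chromosome naming), 4 chromosomes
of 12 Mb each per genome, ~1,000 background genes, and 28 planted genes:
22 homologs at 80–95% identity (orthologs, one tandem paralog at a 3 Mb
gap, one segmented at 6 Mb, one on another chromosome, one tandem at
4 Mb, three planted clusters) and 6 decoys at 35–50% identity. These
sizes keep a full run around a minute on one CPU while still exercising
every rule and boundary; chromosome counts and background density are
configuration, not code.

What passing recovery tests does **not** show about real data: no indel
or domain-gain/loss evolution, no gene families or repeats (so no
near-threshold ambiguity between paralogs), no intron structure (genome
mode sees single-exon CDS), no polyploid homoeologous exchange or
fractionation, and placeholder query sequences rather than real R-gene
proteins. The recovery criteria are correctness checks of the mining
logic, not benchmarks of sensitivity on real genomes.

## Published-count consistency checks

The reporting module re-derives each published study total from its
printed components (per-species CDRH counts → 660; NLR+RLK+RLP → 431;
cluster subtotals → 55 and 87; paralog/ortholog table columns and row
partitions; per-disease RGA/non-RGA partitions). Eight checks reproduce
internal inconsistencies of the printed source tables — column sums and
row partitions that do not match their printed totals, and one narrative
count whose parts sum to 61 rather than 62. These are shipped as
documented known-failing checks: the checker reports them as failures
with a `documented_discrepancy` flag instead of silently correcting
either side.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere; tabular BLAST subject
  coordinates are normalised to `t_start ≤ t_end` with strand kept
  separately.
* When two sequences admit no positive-scoring local alignment,
  `local_align` returns a degenerate single-pair hit (the best-scoring
  residue pair, score floored at 0) rather than failing; such hits can
  never pass the filters.
* Alignment traceback ties take Biopython's first reported optimum;
  scores (the tested quantity) are tie-free.
* All simulator randomness flows from one integer seed through a single
  generator; equal seeds give byte-identical output files.
* Report tables carry explicit margins, and marginal conservation is
  asserted in tests rather than assumed.
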