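# Methods

## Scope and model

`lipomap` re-implements, as a reusable and testable pipeline, the
comparative-genomics side of lipoate-assembly biology: which enzymes a
prokaryotic genome carries for building or scavenging the lipoyl
cofactor, how those genes are arranged, and which datasets a
phylogenetic analysis of the enzyme families should be built from.

The biological model is as follows. Lipoylation of acceptor proteins
(GcvH, LbpA, E2 lipoyl domains) proceeds either (i) from ACP-bound
octanoate via an octanoyltransferase (LipB or LipM) followed by sulfur
insertion by the radical-SAM lipoyl synthase LipA, or (ii) from free
octanoate/lipoate via an ATP-dependent lipoate:protein ligase (Lpl)
followed by sulfur insertion by LipA or by the two-subunit synthase
pair LipS1/LipS2, which acts together with the FAD-binding
oxidoreductase LipT and is characteristic of (but not restricted to)
sHdr-type sulfur oxidizers. Profile HMMs cannot distinguish ligase
subtypes — fused Lpl(AB), circularly permuted Lpl(BA), bipartite
LplA+LplB, or the sulfur-oxidizer-associated sLpl(AB) — so every
detected ligase is labelled `Lpl` and subtypes are resolved from two
context signals: the protein's domain architecture and the genomic
neighborhood / co-occurring synthase type.

## Annotation (module `annotate`)

Every protein is labelled by its best profile-HMM hit among those at or
above the model's trusted cutoff (inclusive `>=`, the HMMER convention
for curated thresholds). Ties are broken by catalog priority and then
lexicographic accession, plus envelope coordinates, so annotation is a
total order and therefore independent of hit-file order. Hits on
accessions absent from the catalog are ignored with a warning; hits
referencing proteins absent from the FASTA abort the run.

Ligases are screened for the accessory LplB domain (Pfam PF10437). A
fused architecture is called when an accepted accessory hit overlaps
the catalytic envelope by at most 50 % of the shorter envelope
(envelopes of abutting domains fray; a stricter rule would miss real
fusions, a looser one would accept nested false hits). Envelope
midpoints order the domains: catalytic-first is the canonical Lpl(AB)
fusion, accessory-first the circularly permuted Lpl(BA).

The HMM catalog is an editable JSON config. Defaults use public
Pfam/TIGRFAM accessions where a well-known model exists (PF10437,
TIGR00545, TIGR00214, TIGR00510, PF01597, PF00364, TIGR00121,
TIGR00433) and named `HMSSS_*` placeholders for sulfur-metabolism
extension models; trusted cutoffs are stored in the catalog because
the tabular hit format does not carry model thresholds. Any single
sHdr marker model sets the sHdr presence flag.

## Gene context (module `context`)

A gene cluster is a maximal run of labelled genes on one contig in
which consecutive labelled genes are separated by at most `max_gap`
intervening unlabelled genes. `max_gap` defaults to 3: large enough to
tolerate the small uncharacterized insertions seen inside real
lipoate-assembly operons (e.g. transporter or amidotransferase genes),
small enough to retain operon-scale locality. Clusters partition the
labelled genes: no labelled gene is in two clusters, none is lost.

Arrangements are rendered as canonical token strings
(`lipS1-lpl(AB)-lipT-lipS2`); if the majority of member genes lie on
the minus strand the member order is reversed before joining, so an
operon and its reverse-complement layout give identical strings. Strand
uniformity is not required within a cluster, and a strand tie keeps
as-read order. Coordinates are 1-based inclusive (GFF3) throughout.

## Pathway typing (module `profiles`)

Per-genome profiles count annotated labels; presence flags derive from
the counts. `LipS1S2` requires both subunits; `LD` pools all
lipoyl-domain acceptor labels into one bit. Taxonomy comes from
GTDB-style strings (`d__...;p__...;...`); malformed strings exclude the
genome with a warning rather than aborting a cohort build. Incomplete
assemblies receive no special treatment: absence is absence.

Pathway systems pair a first step with a synthase: LipB/LipA,
LipM/LipA, Lpl/LipA, sLpl/LipS1S2, and the ligase-independent
LipM/LipS1S2 (called only when no ligase is present). A ligase without
any synthase yields "scavenging only". Genomes carrying both LipB and
LipM get both flags and both systems — rare but not forbidden.

Ligase subtype calls apply, in order: circular permutation (B-then-A
architecture → cpLpl(BA)); an unfused catalytic domain with a syntenic
accessory gene → bipartite LplAB; co-clustering with lipS1/lipS2, or
being the sole ligase of a LipS1/S2 genome → sLpl(AB); a LipA genome
without LipS1/S2 → classical Lpl; otherwise undetermined. "Single copy
of the ligase gene" is interpreted as exactly one Lpl-labelled protein
per genome; multi-copy genomes get per-copy calls but are excluded from
the context-based sLpl inference and from the ligase phylo dataset.
Labels are exclusive per protein: a LipM protein is never counted under
the Lpl flag.

## Statistics (module `stats`)

Venn-region counts are exact inclusion/exclusion counts for up to five
presence flags. Conditional co-occurrence is `100 × |A ∧ B| / |A|`,
rounded half-up to one decimal; an empty conditioning set returns an
explicit undefined (None), never 0. Integral percentages print without
a decimal, matching the mixed precision conventions of survey
reporting. Per-phylum tables normalize within each phylum and are never
pooled across phyla or domains; Bacteria and Archaea are always
summarized separately, over species-representative genomes. External
presence/absence spreadsheets load through a column-mapping config so
published survey tables can be replayed through the same statistics.

## Phylogenetic dataset construction (module `phyloprep`)

Sequence-level normalizations:

* **Syntenic pair concatenation** — a genome's single unfused catalytic
  ligase gene plus its clustered accessory gene are concatenated
  A-then-B to match the fused domain structure; genomes on an explicit
  whitelist are concatenated even without synteny (for biochemically
  characterized bipartite enzymes whose genes do not cluster).
  Ambiguous pairings are skipped with a warning.
* **Circular-permutation normalization** — a B-then-A fusion is split
  at the midpoint of the gap between the accessory envelope end and the
  catalytic envelope start (the only positional evidence available) and
  rejoined A-then-B. The operation is a length-preserving rotation;
  composing with the complementary boundary is the identity.
* **LipS1+LipS2 concatenation** — only genomes with exactly one copy of
  each subunit (paralog exclusion), concatenated LipS1-then-LipS2.
  Subunits shorter than 60 % of the within-label cohort median are
  treated as incomplete and excluded; the filter needs a numeric
  threshold and 60 % separates truncated fragments from full-length
  enzymes given the narrow length distributions of these families.
* **Similarity clustering** — greedy incremental clustering, longest
  record first, joining the first representative at or above the
  identity threshold (default 0.70). Identity is estimated
  alignment-free as the Jaccard similarity of 4-mer sets; at a
  threshold of 1.0 only exact duplicates merge (the k-mer estimate
  alone cannot certify exact identity, so that case compares sequences
  directly).

Seven datasets are built (the ligase/transferase superset rooted by
biotin ligase BirA; three clade-3 ligase variants differing in whether
LipM and cp-normalized records are included, rooted by classical
clade-2 ligases; the LipS1+LipS2 concatenation; and individual
LipS1/LipS2 sets rooted by biotin synthase BioB). Every candidate
record appears in the dataset manifest exactly once, included or
excluded with a reason.

External steps are emitted as command manifests only (MAFFT alignment;
BMGE trimming with entropy threshold 0.95, minimum block length 1,
BLOSUM30; IQ-TREE with model selection, 2,000 SH-aLRT replicates,
aBayes, and 2,000 ultrafast-bootstrap replicates). Records shorter than
80 % of the longest record in a dataset are aligned in a second
`--add-fragments --keeplength` pass so single-domain or truncated
sequences do not erode the full-length alignment. Nothing is executed
by the library; alignment, trimming and tree inference correctness is
out of scope.

## Synthetic data (module `simulate`)

The generator emulates exactly the features the pipeline keys on:
contigs with ordered genes; planted clusters with defined arrangements
(`lipS1-slpl(AB)-lipT-lipS2`; the archaeal `lipS2-lplA-lplB-lipS1`);
fused / split / circularly permuted ligase architectures (default mix
0.6 : 0.25 : 0.15); decoy genes; and noise knobs for missing genes,
paralog injection and contig splits (all default 0 — the cohort
emulates complete, quality-filtered representative genomes). The
default cohort is 150 genomes (100 bacteria, 50 archaea) spread
unevenly over 13 pathway types, reflecting that octanoyltransferase
routes dominate in bacteria while scavenging-only genomes are common
in archaea.

Protein sequences are random strings over the 20-letter alphabet with
label-specific length distributions; hits are simulated (planted labels
get bitscore = trusted cutoff + a positive margin, decoys below-cutoff
hits or none), not searched. This deliberately does **not** emulate
real homology, HMM score distributions, annotation errors between
related families, or alignable sequence evolution — so passing tests
demonstrate the correctness of the decision logic downstream of an HMM
search, not the sensitivity/specificity of any HMM library. Split
bipartite pairs are laid adjacently (the two-gene form is a syntenic
pair); loose genes are separated from planted clusters by more than
`max_gap` decoys so planted arrangements are unambiguous; minus-strand
clusters are laid in reverse gene order so the coding-strand reading
reproduces the template.

Ground truth is updated after perturbations by simulate's own rule
table, intentionally independent of the typing module it is used to
test.

## Determinism and numerical choices

All randomness flows through one seeded NumPy generator per cohort;
fixed seeds give byte-identical output files. The pipeline writes no
timestamps; the run log records package version, parameters and
SHA-256 checksums of inputs, so whole output trees are reproducible
byte-for-byte. Cutoff comparison is inclusive; all tie-breaks
(annotation, clustering order, representative selection) are total
orders.

## Problem sizes

The test suite and the acceptance script run the pipeline at cohort
sizes of 10–150 synthetic genomes (about 4,000 proteins at the
default), which exercises every code path in seconds. A
catalogue-scale survey (tens of thousands of proteomes) uses the same
interfaces: per-genome work is independent and the pipeline is
single-pass over hits and genes.

## Known limitations

* The HMM catalog's default accessions beyond PF10437 are placeholders
  to be reviewed against the curated model list of the annotation
  toolkit in use.
* The neighborhood criterion (`max_gap` = 3) is a configurable choice;
  published surveys rarely state theirs numerically.
* The k-mer identity estimate underestimates identity for highly
  repetitive sequences and is not a substitute for alignment-based
  clustering when thresholds must be calibrated.
* Tree topologies, branch supports and full-scale re-annotation are
  not reproduced here: external tools are orchestrated via manifests
  only, and desk-scale synthetic sequences are not alignable homologs.
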