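# Methods

`ecrfoot` analyses candidate *cis*-regulatory elements of a conserved
genomic domain (the motivating case is the ~500-kb imprinted *Peg3*
domain, whose middle region carries 18 short evolutionarily conserved
regions, ECRs) through five connected procedures. Each is implemented
in `src/ecrfoot/` and exercised end-to-end on synthetic data with known
ground truth.

## Conserved-element calling (`conservation`)

Two genomic intervals are compared by affine-gap alignment (match +1,
mismatch −1, gap open −2, gap extend −1; a gap of length *k* costs
open + (*k*−1)·extend; `N` never matches). A conserved element is any
maximal aligned block **longer than 50 bp** with **identity strictly
greater than 0.75**, where identity = matches / aligned columns and gap
columns count against identity. Both thresholds are strict and
configurable (`ConservationParams`).

`find_conserved_elements` enumerates local alignments bl2seq-style:
take the best local alignment, call blocks from it, mask the aligned
region with `N` in both sequences, repeat while the score can still
contain a minimal qualifying block.

Block boundaries within one alignment come from the *score* signal,
not from identity windows. Aligned random background reaches ~0.6
column identity (the affine aligner buys matches with gaps), so
threshold-identity windows smear boundaries; per-column scores separate
a conserved block (+0.56/column at 0.78 identity) from background
(negative drift) much more sharply. The procedure is:

1. extract the best-scoring segment of the per-column affine scores
   (iterated max-subarray; ties leftmost-then-longest);
2. refine each end while its terminal window (half the minimum block
   length) fails the identity threshold, then trim flanking non-match
   columns;
3. a refined segment passing the length/identity filter is emitted and
   the flanks are decomposed recursively; a long failing segment —
   typically several blocks chained through background — is split at
   the maximum drawdown of the cumulative score (the bridge bottom)
   and both halves retried.

On the generator's standard conditions (three 150-bp blocks at 0.85
identity in 200-bp random flanks) this recovers planted blocks with
≥80% reciprocal overlap in >95% of trials; a relaxation of the
thresholds never loses coverage, though adjacent elements may merge
into one longer call (hence the monotonicity test checks coverage, not
element-set inclusion).

## Ortholog search and presence matrix

`ortholog_search` is a seed-and-extend nucleotide search: exact 11-mers
of the probe are hashed over the target, seeds are clustered by
diagonal, clusters are extended by local alignment of the probe against
a window, and hits with score ≥ 30 are kept (one best hit per
overlapping locus, both strands searched; seed words containing `N` are
skipped, so long `N` runs split seeding). The presence matrix records,
per species × probe, the maximum hit score, with per-probe species
counts and their mean. The score is this package's alignment score; it
is not numerically comparable to scores of other search engines.

## Phylogenetic footprinting (`footprinting`)

Each element's ortholog set is aligned to a chosen reference species
pairwise (global affine-gap), and the pairwise alignments are merged on
reference coordinates (reference-anchored, not progressive — this
mirrors pairwise-alignment practice and keeps all coordinates on the
reference). Insertions relative to the reference open flagged
reference-gap columns sized to the longest insertion; ungapping any row
reproduces the input sequence exactly. Footprints are maximal runs of
columns identical, non-gap and non-`N` in every row, of length ≥ 6
(the shortest library motif; configurable).

## Motif scanning and enrichment

Motifs are IUPAC patterns; the shipped library is the four motifs
recurrently associated with the ECRs of this domain: E box `CAGCTG`,
PITX2 `GGGATTA/TAATCCC`, NF-κB `GGAATTTT/AAAATTCC`, RFX1 `CCATGG`.
Scanning reports every matching start position (overlaps counted) on
the forward strand, plus minus-strand hits via the reverse-complement
spelling; a palindromic pattern (E box, RFX1) yields one hit per
position. Per (element, motif), the matrix records total hits, species
with sequence, species with ≥1 hit, and ratio = total hits / species
with sequence (it can exceed 1); a cell is **enriched iff the ratio is
strictly greater than 0.5**. Species with no identified ortholog are
excluded from the denominator.

## In-silico COBRA (`cobra`)

Bisulfite conversion turns every C into T except 5-methyl-C at CpG
sites (top strand by default; the bottom strand converts on its own
sense with CpGs mapped through the palindrome; incomplete conversion is
available as a per-C retention probability, default 0). PCR requires
both primers to match the converted template exactly and uniquely, and
rejects any primer whose footprint overlaps a CpG (its annealing would
depend on methylation).

An enzyme's informativeness class is always **derived per amplicon**:
the amplicon is converted under both extremes; recognition sites
present only in the unmethylated conversion (completed by CpG→TG, e.g.
FokI `GGATG`, HphI `GGTGA`) make the enzyme unmethylation-indicating;
sites requiring the retained CG (TaqI `TCGA`, BstUI `CGCG`, HpyCH4IV
`ACGT`) make it methylation-indicating; identical site sets, or
differential sites in both directions, are uninformative. The assayed
CpGs are those overlapping a differential site — note an enzyme like
BstUI assays two CpGs jointly, so its digested fraction estimates the
*joint* methylation of the pair, not the per-CpG marginal.

Digestion cuts the converted duplex at each site's cut position
(`cut_offset` from the 3′ end of the site on the site's strand; one cut
point per site models the double-strand cut); fragments always sum to
the amplicon length; cuts landing outside the amplicon are skipped with
a warning.

Quantification assigns bands to the digested or undigested allele by
fragment length within ±2 bp (gel resolution; co-migrating fragments
pool). Since each cut molecule contributes one fragment to *each*
digested band, the digested-molecule signal is the mean over expected
digested bands of intensity / fragment multiplicity; percent
methylation is 100·digested/total for a methylation-indicating enzyme
and 100·undigested/total for an unmethylation-indicating one.

Hypo/hypermethylation versus a matched normal is called from replicate
measurements (≥2 per group, three in all analyses here): the verdict
requires |Δmean| > 10 percentage points **and** a two-sided Welch
t-test rejecting at α = 0.05; both knobs are configurable. With three
replicates the Welch test is mildly conservative (noise-only call rate
≈ 0.03 at α = 0.05), which the acceptance checks measure with the
minimum-difference rule disabled.

## Enhancer-state profiling (`epigenome`)

Intervals are 0-based half-open everywhere; `[0,10)` and `[10,20)` do
not overlap, and any overlap ≥ 1 bp counts (configurable). Per
(element, tissue): H3K4me1 ∧ H3K27ac → active, H3K4me1 only → poised,
H3K27ac only → acetyl-only, neither → none; a hypomethylated flag is
carried alongside. Breadth across tissues: an element supported
(active/poised by marks, hypomethylated, or either — default either)
in a **strict majority** of tissues is ubiquitous; in ≥1 but not a
majority, tissue-specific; otherwise inactive. "Majority" is
formalised as strictly more than half so the boundary (exactly half →
tissue-specific) is testable.

## Synthetic data (`synthetic`)

The generators define the study conditions:

* **Ortholog sets** — one random ancestor, independent lineages (star
  phylogeny), per-site substitution to one of the other three bases
  with equal probability (Jukes–Cantor-like), default rate 0.05 per
  site per lineage (moderate divergence at a conserved locus). Planted
  motifs are copied unmutated into every species. Indels are off by
  default; when enabled, single-base indels only, never inside planted
  motifs, keeping truth coordinates well-defined.
* **Genome pairs** — independent random flanks (200 bp) around shared
  blocks (150 bp, identity 0.85) planted in the same order in both
  genomes; identity < 0.25 is rejected as indistinguishable from
  background.
* **COBRA gels** — *n* molecules, each CpG methylated independently at
  its fraction; molecules converted and digested (unique methylation
  patterns digested once); band intensity = molecule count per
  fragment length × (1 + Gaussian noise), clipped at 0.
* **Tissue tracks** — peaks overlapping each element exactly as its
  assigned state implies, with up to 50 bp of random padding, plus
  decoy peaks placed clear of all elements.
* **Reference collection** — a fixed-composition synthetic
  cross-species collection in the standard survey layout
  (`species|ECRn` multi-FASTA): 18 element sets over a 45-mammal
  eutherian panel, averaging exactly 20 species per element, mouse
  always present; rodent-biased membership and shorter elements with
  fewer species. Motif content is planted and made *exclusive*
  (accidental occurrences of the library motifs are scrubbed by
  deterministic point edits outside planted sites), so motif counts
  are exact ground truth; the 20 ECR18 orthologs carry 34 E-box sites
  (two in 14 species, one in six; 1.7 per species) and one PITX2 site
  each. The seed varies the sequences, never the composition.

All generators are deterministic for a given seed and platform-stable
(seed streams derive from explicit integer key sequences, not string
hashes).

What the generators do **not** emulate: realistic phylogenies (no tree
structure, no rate variation), context-dependent mutation (no CpG
hypermutability), structural variation beyond single-base indels, PCR
amplification bias, or gel smile/background. Passing tests therefore
demonstrate correctness of the algorithms under controlled conditions,
not performance on real genomes.

## Problem sizes and numerical choices

The test suite and acceptance script use deliberately small instances
chosen as adequate for their statistical checks: 1.25-kb genome pairs
(3 planted blocks) over 200 trials for recovery; 10,000 molecules and
2% noise for gel quantification (binomial SD ≈ 0.5 points, tolerance
±3); 1,000 noise-only trials for the false-positive rate (3 binomial
SD ≈ ±2.1 points around α). Floating-point segment scores use an
absolute tie tolerance of 1e-9. Alignment tie-breaking follows the
underlying aligner's first-reported optimum; the symmetry test
therefore allows a ±5 bp slack on swapped coordinates.

## Known limitations

* Quantification assumes the two-allele band pattern of a single
  informative site region; amplicons whose digested fragments co-migrate
  with the undigested band within gel tolerance are rejected rather
  than resolved.
* The reference-anchored merge does not optimise column homology among
  non-reference species (no progressive refinement); footprints are
  slightly conservative where insertions cluster.
* The ortholog search reports one best hit per locus and does not
  chain split hits across long gaps.
* Breadth calls treat all tissues equally; there is no weighting by
  assay quality or tissue relatedness.
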