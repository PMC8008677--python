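# Methods

`phagering` reimplements, as a self-contained and testable pipeline, the
computational procedure used to discover complete phage genomes in
whole-community gut metagenome assemblies and to characterize them:
circularity screening, marker-based classification with stop-codon
reassignment, dereplication, CRISPR-based host prediction, anti-CRISPR
filtering, diversity-generating retroelement (DGR) detection, marker
clustering with a UPGMA guide dendrogram, and length-normalized virome
abundance.  Because the original survey's inputs are thousands of external
assemblies, every stage here is exercised on synthetic communities with
planted ground truth; this note records the models, the defaults and why,
the numerical choices, and what the synthetic conditions do and do not show.

## Circularity screening

Short-read assemblers emit a circular genome as a linear contig whose ends
repeat the assembly k-mer: the screen calls a contig circular when its first
r bases exactly equal its last r bases for some r in [50, 200] (the longest
qualifying r is reported; candidates are enumerated in O(n) with a Z-array).
The repeat window is a filter, not a cap: terminal repeats longer than
200 bp are reported as non-circular with a distinct reason code.  Exact
matching is used (no mismatch tolerance) because assembler-produced terminal
overlaps are exact k-mer artifacts; `N` never matches.  Circular contigs are
canonicalized by trimming the duplicated suffix and rotating to the
lexicographically least rotation (Booth's algorithm), so any rotation of the
same genome maps to one representative.

## Gene calling and amber reassignment

ORFs are called deterministically as maximal start(ATG/GTG/TTG)-to-stop
frames of at least 30 codons on both strands, with origin-spanning ORFs on
circular contigs (the sequence is scanned doubled).  ORFs that run off a
linear contig edge without a stop are emitted as `partial`; this keeps the
containment property that re-reading TAG as glutamine never loses or
shortens an ORF.  Gene-boundary accuracy in the style of a trained gene
caller is not a goal; the pipeline contract only needs protein sequences for
profile search.

A subset of gut phages recode the amber stop TAG as glutamine.  The decision
is made per contig: an externally supplied amber-suppressor-tRNA annotation
dominates (tRNA scanning itself is out of scope and treated as an input);
otherwise a coding-density heuristic compares the fraction of bases covered
by ORFs under the two codes and selects amber-gln when the gain is at least
10 percentage points.  Density for this comparison is measured over ORFs of
>= 60 codons: short spurious open frames arise at similar rates under either
code and would dilute the fragmentation signal left by read-through TAGs,
whereas genuine genes fragmented by TAG mostly fall below 60 codons.  On
generated communities this separates the codes by a wide margin (recoded
genomes gain >= 30 points, standard genomes <= 2).

## Marker profiles and two-round classification

Marker detection uses fixed-width position-specific log-odds models (natural
log, uniform background, 0.5 pseudocount per residue per column, columns
with > 50% gaps dropped) instead of full profile HMMs with insert/delete
states: the contribution being reproduced is the decision rule, not the
search engine, and the contract — hit / no hit at an e-value — is preserved.
Scoring is the best ungapped local alignment of a protein against the model
columns, computed for all proteins at once by a vectorized dynamic program
(E[i,j] = max(E[i-1,j-1], 0) + S[i,j]).

Significance is calibrated per profile by scoring 500 seeded i.i.d.
background decoys and fitting a Gumbel location/scale, the classical null
for ungapped local alignment; the e-value of a score is the Gumbel survival
multiplied by the search space (number of proteins x number of profiles).
Calibration seeds derive from the profile name, so packaged profiles carry a
stable, reproducible null.

Classification is two-round: a relaxed search (e < 0.05) of standard-code
proteins from all (circular, canonicalized) contigs; contigs with any hit
are re-assessed for amber recoding, re-called, and re-searched at e < 0.01.
A contig is classified as phage when it is longer than 3000 bp (strictly)
and carries a round-2 hit to a terminase (TerL), major capsid (MCP) or
portal profile; hits to other phage profiles keep a contig in the round-1
set but do not qualify it.  Multiple marker hits aggregate as
best-hit-per-category.

The three packaged marker alignments are synthetic families (diverged copies
of random ancestral proteins, fixed seed, `scripts/make_marker_msas.py`);
they are stand-ins that make the search self-contained and are labelled
synthetic in file and record names.  Consequences: planted marker genes are
emissions from these profiles, so the funnel tests measure the decision
rule's behaviour (two rounds, thresholds, recoding, length rule), not
cross-family remote homology detection, which a fixed-width model would
understate on real data.

## Dereplication and protein clustering

Genomes are dereplicated greedily (longest first) at >= 95% ANI over >= 80%
of the shorter genome's length; the original tools' coverage denominator is
not printed in the survey's methods, and the shorter genome is the cited
tools' convention.  ANI is estimated by exact shared 16-mer anchoring,
grouping anchors by diagonal, merging anchors separated by <= 100 bp, and
comparing bases directly over the merged blocks (both orientations tried;
aligned fraction is the block coverage of the shorter genome).  For the
substitution-divergence regime of the synthetic communities this estimator
is exact to within sampling noise; it does not model indel-rich divergence,
where a banded aligner would be required.  Circular genomes are compared
after canonicalization and additionally against an origin-shifted copy so a
block split at the rotation origin is not lost.

Proteins cluster greedily (longest first) with local pairwise alignment
(BLOSUM62, affine gaps): a member joins a representative when identity over
the aligned span >= the identity threshold and the span covers >= the
coverage threshold of the member's length (95%/50% for the non-redundant
set; 50% identity for marker and Acr clustering).

## CRISPR host prediction

Spacers are matched ungapped from exact 8-mer seeds on both strands with no
low-complexity masking; a match is accepted at >= 95% identity over the
aligned span covering >= 95% of the spacer length.  On a 32-nt spacer this
accepts one mismatch (96.9%) and rejects two (93.75%).  Matches on circular
genomes cross the origin.  Host taxa propagate from the spacer's source
lineage at each rank; phages targeted by spacers of two or more genera are
flagged, as are protospacers found verbatim in more than one phage genome
(cross-targeting).

## Anti-CRISPR candidate filtering

The Acr prediction score is an input in [0, 1] (the survey's trained model
is external); what is implemented is the filter: proteins are clustered at
50% identity, each cluster's mean score is computed, directons (maximal runs
of adjacent co-oriented ORFs with intergenic gap <= 250 bp — the unit is not
defined in the source and 250 bp is this package's choice) are built from
the ORF table, and a protein passes iff mean score >= 0.9, directon <= 5
genes, an HTH-domain protein in its own directon, and no strong database hit
for the cluster.  The HTH criterion is satisfied by any member of the same
directon (self included); widening to neighbouring directons is possible via
the flag but not the default.

## DGR detection and the adenine-bias test

DGRs copy a template repeat (TR) over a variable repeat (VR) through an
error-prone reverse transcriptase (RT) that misincorporates at template
adenines.  Detection is two-stage around an annotated RT locus (RT
annotation is an input): stage 1 finds near-exact repeat pairs (>= 80 bp at
>= 85% identity — thresholds chosen here for typical 50-150 bp TRs) inside a
10-kb RT-centered window by k-mer-anchored diagonal scanning; stage 2
re-searches each template genome-wide, ungapped, at >= 75% identity over
>= 50% of the template, on both strands.  With a seed word of 4 essentially
every diagonal carries a seed, so stage 2 evaluates all offsets (a
window-sum prefilter keeps it fast); "longest segment at identity >= t with
match endpoints" is solved exactly by a prefix-staircase search.

The hallmark statistic formalizes the qualitative observation that
substitutions concentrate at template adenines: each aligned template column
counts as substituted once if any VR differs there; under the null that
substituted columns fall on template positions at random, the number landing
on adenines is Binomial(n_substituted, f_A) with f_A the adenine fraction of
the aligned template, and the one-sided upper tail is reported.  A repeat is
called hypervariable at p < 0.01 with at least 3 substituted adenine sites.
The count-once-per-column convention matches how substituted sites are
tallied in published TR/VR alignments.

## Marker clustering, profile distances, guide dendrogram, filtering

Cluster alignments are summarized by per-column residue frequency vectors
(gaps excluded, mixed with the uniform background at weight 0.05 — the
mixture form keeps the vectors invariant under duplicating the alignment's
sequences).  The similarity of two profiles is the best ungapped sliding sum
of column scores ln(sum_r fA_r fB_r / q_r) with a minimum overlap of 10
columns, and the distance is d = -ln(S_AB / min(S_AA, S_BB)), clamped to
[0, 10] (non-positive cross-similarities map to the cap).  A hand-rolled
UPGMA (node height = join distance / 2, lexicographic tie-breaking) builds
the guide dendrogram; maximal subtrees whose root height is below 1.5 become
merged-tip groups.  Depth is measured as node height above the leaves —
whether the source measured from root or leaves is not stated, and
leaf-height is the natural reading for an ultrametric tree; the threshold is
a parameter.

Alignment columns are filtered out when more than 50% gapped or when
homogeneity < 0.1.  Homogeneity is normalized conservation: (mean pairwise
BLOSUM62 score of the column's residues − expected random-pair score) /
(mean self-score of those residues − expected random-pair score), clipped to
[0, 1]; an all-identical column scores exactly 1 and a background-random
column ~0.  The exact formula of the cited filtering tradition is not
printed anywhere; this definition is pinned and configurable.

Maximum-likelihood tree inference is out of scope; the module exports the
filtered alignment for external tree builders and provides UPGMA internally
for tests.  The gene-sharing network weights an edge between two genomes as
−log10 of the hypergeometric upper tail of sharing at least the observed
number of protein clusters given each genome's cluster count and the cluster
universe; edges below weight 2 (p > 0.01) are dropped.

## Read recruitment and fractional abundance

Reads are decontaminated against a decoy database by an exact 31-mer screen
(a read sharing >= 50% of its k-mers with a decoy is removed — emulating the
survey's human/vector pre-mapping), then recruited by exact-seed ungapped
matching: a read goes to the genome(s) with the most matching bases at the
best diagonal, requiring >= 90% of the read to match; ties split 1/t across
the tied genomes (the source does not state its multiread handling).  SAM
from an external mapper can be supplied instead and is parsed for counts.
Per-genome coverage is tracked in 100-bp windows.

Fractional abundance is the reads-per-base share
F_i = (c_i/L_i) / sum_j (c_j/L_j) — the survey cites an earlier study for
the definition without printing it; this is that lineage's standard form.
Fractions sum to 1 whenever any read is recruited; detection means >= 1
recruited read.

## The synthetic communities (study conditions)

Defaults, chosen once: 20 circular phage genomes of 15-35 kb, 5 circular
plasmid decoys of 8-15 kb, 10 linear fragments of 4-10 kb; terminal repeats
drawn uniformly from 50-200 bp; 3 phage genomes amber-recoded; uniform base
composition (GC configurable); genomes are gene-dense (random 120-300 aa
proteins, 15-40 bp intergenic spacers, stops TAA/TGA), as real phage and
plasmid sequences are — this matters for the coding-density heuristic.  The
lengths sit at the lower end of the real gut-phage size spectrum (median
~45 kb in surveys) so that whole-pipeline simulations remain desk-scale;
they are above every length threshold in the pipeline, so no decision rule
is affected.  Phage genomes carry one emission of each marker profile;
plasmids and linear fragments carry none, which makes the funnel's
false-positive measurement a test of the e-value calibration alone.
Recoded genomes place one TAG read-through glutamine mid-marker-gene and
recode ~80% of glutamines in background genes.  DGR cassettes plant an RT
gene, a template repeat (>= 5 adenines enforced), and VR copies whose
mismatches are confined to template adenines (a chosen fraction mutated,
optional background noise, default 0).  CRISPR spacers are 32-nt substrings
of planted phages (either strand) labelled with a host genus, plus
non-targeting random decoys.  Reads are error-free 100-mers (optional
uniform substitution rate) sampled with probability proportional to
abundance x length, which makes the expected recovered length-normalized
fraction equal the input vector; reads cross the origin of circular genomes.

What passing these conditions does not show: performance under sequencing
error, assembly artifacts, strain mixtures, remote marker homology, or
compositional bias; the generator is deliberately clean so that each stage's
decision logic is tested against unambiguous truth.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; seeded runs are byte-reproducible.  The
acceptance script exercises the funnel on 5 default communities, a
30-genome dereplication bench, 200 null and 100 signal DGR replicates, 100
random UPGMA matrices, and a 10-genome / 50,000-read abundance recovery —
sizes at which every property measured is stable to well within its stated
tolerance.

## Known limitations

Fixed-width profiles understate remote homology relative to profile HMMs;
the ANI estimator targets substitution divergence; the internal read mapper
assumes near-exact reads (use SAM input otherwise); UPGMA is a guide
dendrogram, not a phylogeny; tRNA scanning, ML tree building, and external
annotation databases are inputs, not components.
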