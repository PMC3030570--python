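# Methods

This note records the models, scoring choices, and simulation conditions
behind `fbxscape`, and what the synthetic experiments do and do not show.

## Similarity search

Local protein alignment is exact affine-gap Smith–Waterman under BLOSUM62
with gap open 11 / extend 1 (a length-L gap costs 11 + L). Significance
uses the Karlin–Altschul form E = K·m·n·e^(−λS) with the standard gapped
calibration λ = 0.267, K = 0.041. Translated (six-frame) search translates
both strands in all three frames; stop codons terminate searchable
segments, so no local alignment crosses a stop. Hits are reported on
forward-strand coordinates; an E-value cutoff of 1 is the default for the
initial domain search (permissive on purpose: the domain is short and
diverged family members must not be missed), 10⁻⁵ for reference searches
inside annotation windows. All cutoff and matrix constants live in
`PipelineConfig`.

The kernel is a scalar dynamic program compiled with numba when available,
with an exactly equivalent vectorised numpy fallback; the two are asserted
equal in the test suite. PSSM domain models are log-odds matrices built
from a consensus with a uniform mismatch probability; the default
reporting threshold is half the maximum attainable window score.

## Spliced protein-to-genome alignment

The gene-structure aligner is a reduced similarity-based prediction DP in
the GeneWise tradition, with states for codon matches (BLOSUM62), protein
and genome-codon affine gaps, frameshift "codons" consuming 2 or 4 bases
(−20), in-frame stop codons aligned at −15, and GT..AG introns openable at
all three codon phases with a length-neutral −10 and a 20-base minimum.
A codon split by a phase-1/2 intron contributes no residue score; this
keeps the donor running-maximum recurrence exact and O(n·m) and costs at
most a few score units per intron. A premature stop is an in-frame stop
aligned at least one residue before the aligned protein end, so a
reference's own terminal stop is never an event. Alignments scoring below
50 are not reported; the scale is calibrated so a perfect ~40-residue
domain match scores about 200. The traceback runs as an explicit state
machine over the stored score planes so the reconstructed path always
reproduces the forward value exactly.

Known limitation: because introns are length-neutral, two same-family gene
copies separated by a short spacer can in principle be bridged by one
alignment. The annotation flow neutralises this by acting on the single
converged coding region after window trimming (below); windows given
directly to `spliced_align` do not have that protection.

## CTT and consensus annotation

Each candidate locus (a translated-search domain hit) gets a 10-kb window
centred on the hit, clipped at chromosome ends. Per round: rank all
references by their best translated-search bit score in the window
(E < 10⁻⁵); spliced-align the top reference on both strands; if the
predicted coding region covers the target domain interval, converge,
otherwise trim that region's span off the window (never any target base —
when a region straddles the target boundary only the non-overlapping side
is trimmed and the case is flagged) and repeat, at most six times. After
convergence, the final annotation acts on the converged coding region plus
a 300-bp pad, not the whole residual window, so tandem neighbours left in
the window cannot attract the model. The top two references (top three
when more than two are similar) are aligned; the locus is classified
pseudogene iff at least two alignments carry a frameshift or premature
stop, coding iff at least two are event-free, otherwise unresolved.
Consensus is on the verdict class only, not on exon-level structure. Ties
between equal-scoring references break lexicographically. Re-annotation of
already-annotated loci excludes the locus's own protein from the ranking.

## Orthology and taxonomic scale

The orthologous-group graph connects proteins whose local alignment passes
E ≤ 10⁻⁵; raw weights are −log₁₀E capped at 200 and then normalised by the
squared ratio to the geometric mean of the endpoints' best weights. The
normalisation matters: family members share the domain, so the raw graph
is dense and near-uniform and Markov clustering at inflation 4 would
return one giant component; after normalisation each gene's strongest
partners stand out and MCL recovers the planted families with ~95+%
purity. MCL alternates expansion (matrix square) and inflation (entrywise
power 4, column renormalisation) with entries below 10⁻⁸ pruned, and reads
clusters off the attractor components. Bins are distinct-species counts;
orphan and bins 1–4 are STS, bins 5+ LTS. Oversized clusters (>1000) are
split by cutting the longest internal branches of their NJ tree.

## Gene trees and reconciliation

Neighbor joining is implemented directly with deterministic tie-breaking
(canonical-label pairs), negative branch lengths clamped at zero; its
topologies are cross-checked against scikit-bio's NJ in the tests.
Reconciliation is standard LCA duplication–loss parsimony: a node is a
duplication iff its mapping equals a child's mapping; losses are the
species-tree branches skipped along mapped child paths, attributed to the
sibling branches they orphan. Unrooted gene trees are rooted on the edge
minimising duplications + losses (ties: fewer duplications, then canonical
edge order). Aggregation over clusters follows the ≥4-species rule:
single-species clusters contribute their size as terminal-branch gains and
2–3-species clusters are excluded. Birth/death scenarios simulated along
the packaged 18-species tree use Poisson per-branch gains and losses;
scenario gene trees are built from additive distances combining species
patristic distance with the gain-branch geometry carried in gene labels.

## Selection analysis

For each query, the two closest non-self references (by bit score) are
codon-aligned with the query via progressive protein alignment (closest
pair first, third sequence to the pair profile) threaded back to codons.
The triplet is midpoint-rooted from its pairwise p-distances and the MRCA
sequence reconstructed per nucleotide column by Fitch parsimony, root
ambiguity resolved in favour of the query's state (the MRCA serves as the
query's comparison partner; any unbiased rule differs only at tied
columns). Ka and Ks come from NG86: per-site fractions with nonsense
changes disregarded, pathway-averaged differences excluding stop-crossing
pathways, Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3) (undefined at
p ≥ 3/4 → record filtered). Records with Ks < 0.005 (too similar for a
stable ratio) or Ks > 3 (saturated) are filtered; boundary values are
retained.

The neutrality test fits the GY94 codon model pairwise with equal codon
frequencies (1/61) — simpler than F3×4 and fully specified; the
likelihood-ratio contract is unchanged — by bounded quasi-Newton over
(log t, log κ[, log ω]) with three seeded starts. LR = 2(lnL_free −
lnL_{ω=1}) is compared to 3.84; significant loci are purifying (ω̂ < 1) or
adaptive (ω̂ > 1), the rest neutral. Under ω = 1 simulation (200 codons,
t = 0.3, κ = 2, 200 replicates) the empirical rejection rate is 4–7%
across seed bases, consistent with the nominal 5%. Domain vs non-domain
contrasts reuse the same machinery on the two column partitions of the
triplet alignment.

## Duplication modes

Collinear blocks chain homolog anchor pairs over gene-order ordinals
(both sides strictly increasing, or one decreasing for inverted blocks)
with a match bonus of 10, a gap penalty of 3 per skipped ordinal
(DAGchainer-like), a maximum per-step gap of 10 ordinals, and a minimum of
6 anchors per block. Same-chromosome anchors within the gap window are
excluded (tandem-array structure is not collinearity evidence). Ordinals
are computed over the whole annotation — family loci plus background
genes — because ordinals over family loci alone compress distances and
manufacture spurious collinearity. A pair is tandem when on one chromosome
with at most 10 intervening genes ("proximal" is not numerically defined
in the field; 10 is the configurable default). Block membership takes
precedence over tandem membership (positional evidence is stronger);
everything else is "other".

## Expression

An EST supports a locus when its best local DNA alignment has >95%
identity, covers ≥75% of the read or of the CDS, and spans ≥50 aligned
nucleotides; ties go to the highest identity, then longest alignment, then
lexicographic id. A 25-mer prefilter limits candidate loci (guaranteed
lossless at the identity threshold for the read lengths generated here).
Group contrasts are one-sided Fisher exact tests (exact hypergeometric
upper tail) in the fixed order LTSP>STSP, LTSP>pseudogene,
STSP>pseudogene; the sidedness was validated by reproducing the published
census p-values exactly at printed precision. No multiple-testing
correction is applied, matching how such surveys report raw p < 0.05.

## Synthetic data: what it emulates, and what it does not

The generator plants families sharing a noisy 40-residue domain consensus
(10% per-position substitution per family) and optional C-terminal module
(kelch/LRR/FBA toy consensi). Each family has one founding CDS
(back-translated with uniform synonymous codon choice); members diverge
from it by 5% per-base substitution with stop-creating changes suppressed,
so within-family synonymous divergence is realistic and Ka/Ks against the
reconstructed MRCA is well-behaved. Loci carry 0–3 GT..AG introns
(80–400 bp, phase-uniform). Pseudogene copies receive one or two explicit
lesions (1-bp deletions and/or TAA stop substitutions) recorded in the
truth. Tandem arrays are contiguous same-family runs (gaps 0.6–2.5 kb);
segmental blocks are six collinear two-member families split across two
chromosomes; singleton families spread members across chromosomes with
shuffled order so they cannot line up into fake collinearity. Intergenic
spacers are i.i.d. uniform ACGT with filler gene positions every ~1.2 kb,
giving gene-order coordinates the density of a real annotation. The
default study conditions are 30 coding + 20 pseudogene loci on three
150-kb chromosomes, family size six, and two additional reference-only
homologs per family — the reference collection a real survey would have is
far deeper than any one genome, and the two-reference consensus rule
presumes close references exist.

Passing these tests shows the machinery is correct and calibrated on data
matching its model assumptions. It does not demonstrate robustness to
repeat elements, non-canonical splice sites, codon-usage bias, sequencing
error beyond uniform substitution, assembly gaps, or deep divergence —
none of which the generator emulates.

## Problem sizes

The default test and acceptance runs use the 50-locus genome (one full
pipeline execution, reused across tests), 200 replicates for the LRT
calibration, 50 for omega recovery, 100 per group for the Ka/Ks contrast,
and 24-locus genomes for the duplication-mode contrast — sizes chosen so
every distributional claim has conventional statistical support at
desk scale.
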