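# Methods

This note records the models, conventions and design choices behind
`telandscape`, in the order the pipeline runs them.

## Coordinates and formats

All internal coordinates are 0-based half-open; RepeatMasker `.out`
and GFF3 (both 1-based inclusive) are converted only at the I/O
boundary, so interval arithmetic lives under a single convention.
RepeatMasker strand `C` maps to `-`; the trailing overlap-flag asterisk
is tolerated and ignored; a `class/family` token splits on `/` into
order and superfamily, with a bare order standing in for both.
Superfamily names are case-normalized for lookup but hyphen-preserving
(hAT-Charlie and hAT-Ac are distinct). Records classed as simple
repeats, low complexity, satellites or structural RNAs are retained
with order `Other` and excluded from TE analyses by default, since
these statistics concern transposable elements.

## Content census and comparison

The census sums fragment lengths per superfamily (or order). The
default is the raw sum — overlapping annotations double-count, which is
what "adding fragment sizes" means operationally — with a merged
(disjoint-union) mode available because the gene-overlap stage
explicitly works on merged regions; both can be reported side by side.
Genome fraction divides by assembly size. Fold-change is computed as a
difference of logs, `log2(bp_ref) − log2(bp_other)`, so swapping the
two species negates the value exactly; a superfamily absent from the
other species yields NaN rather than infinity. Core-set membership
uses presence thresholds of ≥1 fragment and ≥0 bp by default
(configurable), and the partition enumerates exactly the non-empty
species-subset cells, as an UpSet plot would.

## Kimura landscapes

Landscapes are bp-weighted by default (each fragment contributes its
length to the bin holding its percent divergence), the convention of
RepeatMasker repeat landscapes; copy-weighting is available. Bins are
width-1 percent intervals [0,1) … [49,50) with an overflow bin at 50
and a separate tally for fragments lacking a divergence value.
Divergences are taken from the annotation column; no CpG adjustment is
applied.

One binning caveat: a burst planted at, say, K = 0.30 puts the
per-copy estimator distribution centred exactly on the edge between
bins [29,30) and [30,31) (per-copy standard deviation is one to two
bins for 1–3 kb copies). Which single bin is heaviest is therefore
essentially a coin flip; the stable statements, and the ones the tests
make, are that the landscape peak lies within one bin of the planted
age and that the mean recovered K per burst is within ±0.015 of the
target.

## Sequence comparison

Pairwise alignment uses an affine-gap aligner (Needleman–Wunsch /
Smith–Waterman; defaults match +1, mismatch −1, gap open −5, extend −1,
a gap of length L costing open + (L−1)·extend). `N` scores zero
against everything and is excluded from match/mismatch tallies.
Identity is matches divided by the shorter input's length (the CD-HIT
convention), so a fragment contained in a longer one can reach 1.0.

K2P distance is the closed form `−½ ln((1−2P−Q)√(1−2Q))` over ungapped
non-N columns, raising a saturation error when the argument leaves the
admissible region. Greedy clustering sorts fragments longer than 1 kb
by length (ties by id) and joins each to the first centroid exceeded
at strictly >70% identity, else founds a new cluster — the longest
member is automatically the centroid. Coverage filtering aligns every
centroid globally to its superfamily's longest centroid (a star
reference standing in for a full MSA) and keeps those covering strictly
more than the superfamily threshold of the reference's columns:
L2 0.80, RTE-BovB 0.60, Rex-Babar / TcMar-Tc1 / hAT-Ac / hAT-Charlie
0.30, and 0.30 for anything else. Strict inequalities follow the
"higher than" wording of the thresholds.

Trees are neighbor-joining (scikit-bio) on the K2P matrix — a
deliberate, documented substitution of a distance method for
maximum-likelihood inference, keeping the package self-contained;
externally computed trees can be supplied as Newick. Bootstrap support
resamples the star-alignment columns with replacement, rebuilds matrix
and tree per replicate, and scores each internal bipartition by the
percentage of replicates containing it.

Ka/Ks is Nei–Gojobori (1986): synonymous site counts averaged over both
sequences (each codon position contributing the fraction of its three
single-nucleotide changes that are synonymous; changes to stop codons
count as nonsynonymous), substitution counts averaged over all
shortest mutational pathways (steps through stop codons counted
nonsynonymous), and Jukes–Cantor correction of pS and pN with a
saturation error at p ≥ 3/4. Note that a single diverged codon can
legitimately saturate (e.g. one synonymous change at a codon with a
third of a synonymous site gives pS = 3); meaningful estimates need
tens of codons.

## TE–gene overlap

Fragments are merged per superfamily into a minimal disjoint cover
(touching intervals merge) before any intersection. Genes decompose
into exons, introns (the gaps between sorted exons — the two always
partition the gene body exactly), and 500 bp upstream/downstream
flanks assigned by strand and clipped at sequence ends. Overlap is
strand-insensitive; a merged TE region spanning several genes counts
once per gene (gene-centric accounting); for multi-part subregions an
interval touching several exons counts once. All interval statistics
are validated against a per-base boolean-array oracle in the tests.

## Tandem repeats

The detector is a simplified tandem-repeat finder, not a TRF
re-implementation: candidate periods come from a k-mer (k = 5) spacing
vote; each candidate locus gets a majority-vote periodic consensus and
a maximal-scoring ungapped extension under the classic weights
(match +2, mismatch −5; the −7 indel weight is accepted for signature
parity but the extension never opens a gap, adequate for
substitution-noise arrays); arrays need score ≥ 50, period ≤ 2000 and
≥ 1.8 copies. Overlapping reports collapse to the highest-scoring
array, except that a smaller-period report scoring at least 85% of an
overlapping harmonic wins — a longer consensus can out-score the true
period by memorizing noise. The detector's contract is planted-array
recovery (period ±1, copy number ±10% at 5% noise) and a ≤5%
false-positive rate on random 1 kb sequence, not bit-identity with TRF.

Survey percentages (`% regions > 500 bp`, `% of those with tandems`)
are rounded half-even to two decimals. "Highly tandem" genes are those
owning a region whose tandem copy number strictly exceeds the
empirical 99% quantile (linear interpolation) of all region copy
numbers — region-level quantiles, so a gene with several moderate
regions is not promoted, and an all-tied distribution selects nothing.

Unranked enrichment is a one-sided hypergeometric test per term with
Benjamini–Hochberg adjustment; terms with fewer than two annotated
background genes are skipped. Ranked enrichment is a weighted
Kolmogorov–Smirnov running sum (hits step up by |score|, misses step
down uniformly; the score is the deviation of maximal magnitude, so
reversing the ranking negates it), with a gene-label permutation null,
`p = (1 + #{|ES_perm| ≥ |ES|}) / (n_perm + 1)`, and BH adjustment.
Term maps are flat two-column tables; no ontology-graph propagation.

## The simulator

The generator emulates the data shape the pipeline consumes, not
genome biology in full. Per species, a fixed-length i.i.d. uniform
ACGT background is painted over — genes first, then TE copies — so
coordinates never shift and the ground truth tiles the emitted FASTA
exactly. Genes get 2–6 exons of 100–300 bp separated by 0.5–1.5 kb
introns (teleost-like magnitudes) with 500 bp buffers. Each burst
draws copies from a per-superfamily random consensus through a K2P
substitution process: the expected transition/transversion proportions
(P, Q) are obtained by inverting the model at the target distance and
rate ratio κ (default 2), so `k2p(P,Q) = K` exactly in expectation; no
indels, no nested insertions. A configurable fraction of copies
(default 0.3) is placed uniformly in free intron space, the rest in
free intergenic space, never overlapping exons or other copies, with a
capacity error raised before any file is written. The emitted `.out`
divergence column carries each copy's realized Kimura-corrected
percent divergence (the quantity landscapes bin), not the raw mismatch
percentage. Tandem plants overwrite a window inside chosen TE copies
(gene-resident copies first) with a noisy periodic motif. An optional
fragmenter splits a fraction of copies into two abutting records to
exercise interval merging. All randomness derives from the single
config seed; identical configs give byte-identical outputs.

What the simulator does **not** model — realistic base composition,
TE nesting and truncation gradients, LTR structure, insertion-site
bias beyond the intron quota, polymorphism — bounds what green tests
show: they certify the statistics and the bookkeeping, not annotation
quality on real assemblies.

## Problem sizes

The test suite and acceptance script run the conservation check on a
two-species, six-superfamily panel of 5 Mb genomes with ~2,100
insertions, burst-age recovery on 120 copies × 1.2 kb per burst,
interval oracles on 50 random 10 kb instances with up to 2,000
intervals, the detector null on 100 random 1 kb sequences, and ranked
enrichment with 1,000 permutations — sizes at which every check is
exact or tightly bounded while the whole suite stays fast.

## Known limitations

- NJ replaces ML tree inference; supports and topologies on real,
  highly heterogeneous superfamilies will differ from an ML analysis.
- The star alignment to the longest centroid underestimates coverage
  for centroids that align well to each other but poorly to the
  reference.
- The tandem detector's ungapped extension loses arrays whose copies
  differ by indels.
- Census merge mode and the landscape's copy/bp weighting are choices
  surfaced as flags because the operational definitions in the
  literature are often left implicit; both variants are computed.
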