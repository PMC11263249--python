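# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mitocomp`. It is the package's own account of its science;
every number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Coordinate model and genetic code

All internal coordinates are 0-based half-open; GenBank 1-based inclusive
coordinates are converted only at the I/O boundary. Circular genomes are
never rotated implicitly: a feature spanning the origin is stored as two
segments `[x, L)` + `[0, y)`, which keeps gene-order extraction stable with
respect to where the deposited sequence happens to start.

Translation uses the mold/protozoan mitochondrial code (table 4), under
which TGA encodes tryptophan and the only stop codons are TAA and TAG. A
CDS whose length is not a multiple of three is translated after truncating
the trailing bases, with a warning; codons containing N translate to `X`
and are excluded from codon-usage counts. ORF scanning accepts ATG, GTG and
TTG as start codons, because TTG starts occur in these mitogenomes; only
regions longer than 300 bp are scanned, on both strands in all three
frames, and overlapping same-frame ORFs reduce to the longest (first start
after the previous stop).

## Composition and region partition

GC content is `(G+C)/(A+C+G+T)`, GC skew `(G−C)/(G+C)`, AT skew
`(A−T)/(A+T)`; N never enters a denominator and an empty denominator yields
an explicit NaN. Whole-genome skews are reported on the deposited strand;
per-gene skews on the coding strand, which is why a gene's skew can differ
in sign from the genome's.

The five-way region partition (core-PCG exon, RNA gene, uORF, intron,
intergenic) assigns every position exactly one class using the precedence
core-PCG exon > RNA gene > uORF > intron > intergenic. The precedence is a
design choice: annotations overlap (uORFs sit inside cox1 introns), and
this ordering makes class lengths well defined while never eroding core
exons. Gaps between exon segments of a split core gene count as intronic
even without an explicit intron feature. Percentages are reported to two
decimals; internal arithmetic is exact.

## Codon usage, RSCU and PCA

RSCU of codon *j* in a synonymous family of size *k* is its count divided
by the family mean; a family with zero total is undefined (NaN) and, for
PCA only, imputed to the family-neutral value 1.0. Under table 4 the stop
family is {TAA, TAG}. PCA runs on the covariance of column-centered RSCU
rows (scikit-learn, full SVD); component signs are fixed by making the
largest-magnitude loading positive so scores are reproducible. Stop codons
are excluded from PCA rows by default and included in reported tables.

## K2P and NG86 Ka/Ks

K2P uses pairwise deletion: columns with gaps or N in either sequence are
dropped, then `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)` with transition proportion P
and transversion proportion Q. When an argument of a logarithm is
non-positive the distance is reported missing with a "saturated" flag.

Ka/Ks follows Nei & Gojobori (1986) with equal pathway weighting and
Jukes–Cantor correction `K = −¾ ln(1 − 4p/3)`:

* synonymous site counts per codon sum, over the three positions, the
  fraction of single-base changes that are synonymous; changes that would
  create a stop codon are excluded from numerator and denominator, so the
  fractions at a position still sum to one and `S + N = 3 ×` codons
  compared holds identically;
* codons differing at 2–3 positions average the synonymous/nonsynonymous
  split over all orderings of the changes, discarding pathways through stop
  codons unless every pathway is blocked;
* codons containing a gap, N, or a stop in either sequence are dropped
  whole; site counts are averaged over the two sequences;
* `Ka/Ks` is reported missing when Ks = 0 or either rate is saturated
  (p ≥ 3/4).

Per-gene summaries are arithmetic means over all unordered species pairs
with defined values.

## Repeat detection

Dispersed repeats: exact k-mer seeds (k = 15 by default, never larger than
the minimum repeat length) are grouped by diagonal (anti-diagonal for the
reverse strand), chained when successive seeds lie within 60 bp, and each
candidate pair is re-scored by edit-distance alignment (edlib); identity is
gap-inclusive, `100 (1 − dist / max(len))`. Defaults min_len = 30 bp and
min_identity = 70% bracket the smallest repeats these genomes show.
Reported pairs contained in a longer reported pair are dropped; output
order is deterministic. The reported score uses match +1, mismatch −2
(gap open −5, extend −2 in the underlying re-alignment model).

Tandem repeats: for every period p ≤ 200 the boolean lag-p match profile is
segmented into runs, bridging isolated 1–2 mismatch gaps; run ends are
trimmed back to a clean match streak (≥ min(p,4) consecutive matches) so
random flanking bases cannot dilute a locus, with the longest exact sub-run
as a fallback candidate. A locus must reach 2 copies, 20 bp, and ≥ 80%
matches against its tiled majority consensus. Smaller periods suppress
redundant multiples covering the same span. Note that the consensus phase
of a tandem array is arbitrary (any rotation of the unit is equivalent),
and a maximal locus may legitimately begin a few bases before a planted
block when the flank happens to continue the pattern.

Both detectors scan the deposited linear coordinates; a repeat split by the
arbitrary origin of a circular genome would be reported as two loci. This
is a known limitation, irrelevant to the synthetic cohorts (which never
plant features across the origin) and conservative on real data.

## cox1 intron position classes

An intron's species coding position is the cumulative exon length 5′ of it
in coding orientation. Mapping to the reference cox1 is protein-guided: the
two translations are aligned globally (match/mismatch scoring, affine
gaps — robust to occasional `X`/`*` symbols), and the species amino-acid
coordinate is carried through the alignment and expanded back to
nucleotides, preserving the within-codon offset. Insertion sites falling in
a reference gap move to the nearest upstream aligned position and are
flagged. Position classes are named `P<1-based nt position>`; a class is
"common" when present in at least `ceil(0.20 × n_species)` species (≥ 4 of
16) and "rare" otherwise. The reference CDS is configurable and recorded in
output metadata; Pcl names are meaningful only relative to it. Intron type
labels (IA, IB, derived, …) are carried through from the annotation, never
inferred.

## Gene order and synteny

The gene order is the signed circular sequence of the 17 canonical markers
(15 core PCGs + rnl + rns; tRNAs excluded by default), sorted by start
coordinate, rotated to begin at cox1, and reflected/sign-flipped when cox1
lies on the minus strand so every order reads +cox1 first. Orders are
compared by the signed circular breakpoint distance — the number of
oriented adjacencies of one order absent from the other, where adjacency
(a, b) is identified with (−b, −a). This gives a computable criterion for
"identical arrangement" (distance 0) used to group species. Synteny blocks
reuse the seed–chain–extend machinery across genome pairs (k = 12, chain
gap 300) with defaults identity ≥ 70% and length ≥ 500 bp; identity is
gap-inclusive.

## Alignment and phylogeny

Multiple alignment is star-progressive: the center sequence (smallest
summed k-mer distance, k = 6, ties broken lexicographically) is aligned
pairwise to every other sequence with affine-gap global alignment
(nucleotide scores +1/−1, open −2, extend −1), and the pairwise gaps are
threaded into one MSA ("once a gap, always a gap"). Protein-coding genes
are aligned codon-aware: translations are aligned and each amino-acid
column expands to three nucleotide columns, so gaps always come in
triples. This is deliberately simpler than iterative refinement aligners;
for the nearly indel-free mitochondrial core genes it is adequate and
exactly reproducible. Columns with gap fraction > 0.5 are trimmed (whole
codons in codon mode).

Five datasets are concatenated from the per-gene alignments: PCG (14
conserved genes), PCG12 (third codon positions deleted), PCGR/PCG12R (rnl
and rns appended), and AA (translated concatenate); missing markers are
gap-padded and partitions recorded. Trees come from canonical neighbor
joining on K2P distances (pairwise deletion) for nucleotides and
Poisson-corrected p-distances for amino acids; Q-matrix ties break
lexicographically and negative branch lengths clamp to zero. Bootstrap
support resamples columns with replacement (seeded NumPy generator) and
reports the percentage of replicate trees containing each full-data split;
replicates whose distance matrix saturates are skipped. Fitch parsimony
scores (exact on the binary-plus-trifurcating-root trees NJ produces)
provide a likelihood-free topology comparison. Monophyly of a taxon set
holds iff some edge bipartition isolates exactly that set, on either side
(unrooted convention).

Full Bayesian and maximum-likelihood inference are out of scope; the
distance/parsimony stack is the desk-scale stand-in whose accuracy is
demonstrated on simulated data (topology recovery and clade monophyly
rates are computed by the acceptance script).

## Synthetic cohorts

The generator emulates a 16-taxon Hymenochaetales-like study set; its
defaults are the package's study conditions, fixed once:

* **Tree**: a 16-leaf tree with a 3-species *Sanghuangporus*-like trio,
  an *Inonotus*-like pair, a 4-species *Porodaedalea*-like clade, a
  paraphyletic *Phellinus*-like group and two outgroups; internal branches
  ≥ 0.02 substitutions/site, terminal branches 0.02–0.12.
* **Substitution model**: two-rate Kimura (K80) with κ = 2.0, simulated
  per branch from the closed-form transition probabilities; branch lengths
  are expected substitutions per site. Per-gene rate multipliers make rps3
  fastest (×1.8) and atp9 slowest (×0.25), with rRNAs at ×0.5 and tRNAs at
  ×0.3. In coding genes, substitutions that would create an in-frame stop
  codon are reverted (a mild purifying constraint that keeps translations
  clean); the K2P estimator-calibration runs use the unconstrained
  non-coding path.
* **Genes**: 15 core PCGs at realistic codon lengths (atp8 50 … nad5 660),
  rnl 3.0 kb, rns 1.6 kb, 25 tRNAs of 72 nt. Root CDSs are drawn from an
  AT-rich "PCG-like" codon-bias profile; planted uORFs use a distinct
  GC-richer "uORF-like" profile, which is what makes the two classes
  separable by RSCU PCA.
* **Architecture**: genes are laid on a circle in the base order
  cox1 nad4l nad5 atp9 cox2 cob cox3 atp6 nad1 rnl nad4 rns rps3 atp8 nad6
  nad2 nad3 (the arrangement shared by the trio), with species-specific
  inversion/transposition events for the other clades; intergenic spacers
  are log-normal (median 500 bp, σ = 0.6, clipped to [60, 4000] × scale)
  with per-species scale factors spreading genome sizes across ~45–160 kb.
* **Planted truth**: cox1 introns at six reference positions (two present
  in 10/16 species, one in 9/16, one private to the trio, two singletons),
  each intron carrying an internal ORF; one exact 500-bp dispersed
  duplicate and one (ACGTT)×8 tandem array per genome; three intergenic
  uORFs per genome. The ground-truth bundle records the tree, patristic
  distances, Pcl plan, gene orders, repeat loci and per-class region
  lengths, and the whole cohort is byte-identical for identical seeds.

What the generator does **not** emulate: indel evolution (so alignment
columns are trivially homologous), intron sequence homology between
species sharing a Pcl, homing-endonuclease evolution, tRNA structure, and
base-composition heterogeneity along the genome. Passing the planted-truth
suites therefore demonstrates correctness of the measurement machinery
under the stated model, not robustness to real-data alignment ambiguity or
annotation error.

## Problem sizes used by the test and acceptance runs

Estimator calibration uses 100 replicates of 10 kb two-taxon pairs at true
distance 0.1; topology and monophyly recovery use 100 replicates of the
16-taxon per-gene simulation (~13 kb PCG supermatrix); planted-truth
recovery runs once on a full 16-genome cohort. The unit-test suite uses a
6-genome cohort for the cohort-level checks. These sizes were chosen so the
whole validation remains a desk-scale computation while keeping Monte-Carlo
noise well below the asserted margins.

## Known limitations

* The paper-scale tool chain this package parallels (BLASTn self-hits,
  Tandem Repeats Finder, MAFFT+Gblocks/Trimal, MrBayes/IQ-TREE) involves
  tool-specific parameters; `mitocomp`'s detectors and aligners are
  deterministic re-implementations of the same ideas, so absolute counts
  (number of repeats, trimmed alignment lengths) are not expected to match
  those tools bit for bit — property-based validation on planted truth is
  used instead.
* NG86 is a counting method; at high divergence it underestimates rates
  relative to ML codon models.
* Bootstrap supports on the trio clade can be conservative for very short
  internal branches.
* Repeats spanning the sequence origin of a circular genome are reported
  as two loci.
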