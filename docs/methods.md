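# Methods

`loopdom` implements a pipeline from binned Hi-C contact matrices to CTCF
loop domains, topologically isolated genes (TIGs), and downstream boundary
statistics, together with a synthetic-data generator that plants known
structure into every input so that each stage can be scored against truth.

## Significance model for binned contacts

Contacts are aggregated into fixed-size genomic bins (default 10 kb). For a
chromosome with total contact count N (upper triangle including the
diagonal), the expected contact probability of a bin pair at genomic
distance d is estimated by an equal-occupancy stratification: bin-pair
offsets within the tested range (default 30 kb to 2 Mb) are split into
strata holding approximately equal total contact counts (default 100
strata), and per stratum

    p_hat = (contacts in stratum) / (N x bin pairs in stratum).

A weighted isotonic regression (non-increasing in distance) then enforces
monotone decay, which stabilizes sparse far-distance strata. The per-pair
p-value is the upper binomial tail Pr[X >= x] with n = N and p = p_hat
(a Poisson tail is available as an option), and Benjamini-Hochberg
adjustment runs across all tested pairs; pairs with q < 0.01 are
significant interactions. The decay is fitted on raw counts and the tested
range follows the 30 kb lower bound; both bounds are configurable because
different analyses of the same data have used a 20 kb lower bound.

**Calibration diagnostics.** The exact tail of a discrete count is
conservative: the achieved level at any cutoff is below the nominal level,
more so where expected counts are small. To diagnose whether the *decay
model* is calibrated we therefore expose randomized
probability-integral-transform p-values, `Pr[X > x] + U Pr[X = x]` with
U ~ Uniform(0,1), which are exactly uniform under the null. Reported
significance always uses the deterministic conservative tail; the
randomized values exist only for calibration checks. Calibration runs use
a deeper null (5e6 contacts per chromosome) so that per-stratum estimation
noise (relative error ~N_stratum^-1/2) is negligible against the binomial
sampling band of the check itself.

## Loop anchoring and the two-step merge

Significant interactions whose anchor bins (extended by one bin by default,
absorbing the one-bin positional uncertainty of loop pixels) each overlap a
CTCF site (the union of oriented motifs and ChIP peaks) become CTCF-CTCF
loops. For shallow libraries an optional rescue takes the top-k
(default 10,000) most significant candidate loops when fewer than k are
significant; it is off by default in the end-to-end caller because on
desk-scale simulations it would flood the call set with null pixels (the
rescue is meant for deep-genome, shallow-coverage libraries).

Redundant loops are merged by a two-step iterative clustering with a 1 kb
overlap window, interpreted as symmetric extension of each anchor by
500 bp. Step 1 (preclustering, 50 rounds): loops are ranked by chromosome
position (left start, then right start), split into even- and odd-rank
sets, and every cross-set pair whose left anchors and right anchors both
overlap within the window is merged into a loop with union anchors; merged
plus retained loops feed the next round, with ranks recomputed each round.
Step 2 (complete): the same merging runs within the single remaining set,
excluding self-pairs, until no pair qualifies. Because union anchors only
grow, overlap is monotone under merging and the procedure converges to the
unique fixed point of naive repeated pairwise merging, independent of input
order (property-tested against a brute-force oracle). Each merged domain
keeps its constituent loops; the *summit* anchors are those of the member
with the smallest p-value (ties: leftmost member) and serve as the working
boundaries. Domain length is the distance between summit anchor midpoints.

## TIG classification and enrichment tests

Only protein-coding genes count, by TSS rather than gene body. A TSS lies
in a domain when `left summit midpoint <= TSS < right summit midpoint`
(half-open, consistent with the global coordinate convention); a TSS in two
overlapping domains counts in each. Domains with exactly one TSS are
single-gene domains and their gene is a TIG. Enrichment of the single-gene
count is tested by permutation: either every domain is re-placed uniformly
at random on its own chromosome preserving length (overlaps permitted), or
every TSS is re-placed uniformly; with n_perm permutations (default 999)
`p = (1 + #{null >= observed}) / (1 + n_perm)`, giving a p floor of 0.001
at the default. Gene-set enrichment uses the two-sided Fisher exact test
with fold = (hits/category) / (total hits/universe).

## Constitutive domains, consensus and clustered CTCF sites

Domains from multiple samples are pooled (as summit-anchor loops tagged
with their sample) and re-merged with the same algorithm; a union domain is
present in a sample when at least one member originated there, and
*constitutive* when present in at least 50% of samples (the figure legend
of the source datasets uses a strictly-greater rule; the threshold is
configurable). Genes of constitutive single-gene domains are cTIGs.
Consensus CTCF sites are peak clusters recurring in more than 30% of cell
types, snapped to the best-scoring overlapping motif's coordinates and
orientation when one exists, otherwise kept with orientation "unclear".
Clustered vs typical CTCF sites follow the ROSE-style construction: peaks
merged within 12.5 kb with summed signal, ranked ascending, both axes
scaled to [0,1]; the transition is the first rank whose forward-difference
slope exceeds 1, i.e. the slope-1 tangent point of the scaled curve.

## Virtual 4C, specificity, boundary features

Boundary-anchored virtual-4C rows read the contacts between the +/-F-bin
neighbourhood of one summit boundary and the opposite boundary bin
(F defaults to 10 bins here; domains spanning <= 2F bins are skipped).
Rows are aggregated column-wise into mean +/- SE profiles; group contrasts
use the two-sided rank-sum test on boundary-to-boundary values (exact for
small tie-free groups, normal approximation with tie correction
otherwise). Boundary fold changes divide library-size-normalized
boundary-to-boundary contacts with a pseudo-count of 1.

Cell-type-specific regulators require (i) normalized Shannon entropy of
the TPM profile below 0.8 (natural log, normalized by log of the sample
count; zero proportions contribute nothing), (ii) maximal TPM above 10,
and (iii) TPM at least 7-fold above the across-sample mean (the mean
includes the high samples) in 1-5 samples. Enhancer activity is H3K27ac
signal per 10 million reads; enhancers never reaching 5 are dropped as
inactive. Within-domain co-activation pairs each enhancer with the gene of
its containing constitutive single-gene domain, cross-domain with the
nearest TSS outside that domain (an interpretation; Pearson by default,
with the comparison by rank-sum on the two correlation distributions).

Conservation profiles aggregate per-base track scores over motif +/- flank
(default 500 bp) in the motif-forward frame (reverse motifs mirrored);
per-motif summaries are means inside the motif span. Variant burden per
motif is split at 1% allele frequency; AF exactly 1% is binned as common so
the boundary case is deterministic.

## Synthetic benchmark

The default configuration is one 20 Mb chromosome at 10 kb bins
(2,000 bins), power-law distance decay with exponent 1.0, and 5e5 expected
background contacts. Fifty loops are planted at fold 10 with anchor
separations uniform on 5-30 bins (50-300 kb), non-overlapping: this is the
CTCF-loop size range where an a-priori binomial power calculation shows a
desk-scale depth still detects fold-10 pixels reliably, and it brackets
realistic CTCF loop sizes. Loop enrichment spreads over a 3x3 pixel
neighbourhood (center weight 1, neighbours 0.5) to exercise summit
selection; counts are Poisson draws from the multiplicative rate
(decay x loop x optional block). Convergent motifs (forward left, reverse
right) sit inside anchor bins, plus unoriented background sites. Gene
placement makes a configurable fraction of planted domains exactly
single-gene. Multi-sample sets contain 30 shared domains (anchor jitter
<= 500 bp, so any two emitted copies differ by <= 1 kb, within the 1 kb
merge window) and 10 private domains per each of 16 samples. Expression
matrices span 53 samples with planted specific regulators at fold 50 in
1-3 active samples over base TPM ~1: direct evaluation of the entropy
formula shows that a single-spike profile needs roughly fold >= 30 in 53
samples to pass the 0.8 entropy cut, so weaker folds would not constitute
plantable truth. Background genes are log-normal with small per-sample
noise (entropy ~1). Conservation adds 0.3 inside boundary motifs over a
0.2 +/- 0.1 baseline; variants are Poisson at 0.25/bp with the boundary
rate multiplied by 0.2 (the rate is set so an undepleted motif span
averages ~5 variants, giving stable ratio estimates at a few hundred
motifs); enhancer activity targets a Pearson correlation of 0.8 with its
gene. All generators are deterministic given the config seed (independent
named streams per generator).

What passing these tests shows — and does not. The generator matches the
significance model's own assumptions (Poisson counts, clean power-law
decay, no compartment structure, no mappability or copy-number artefacts,
single chromosome, no trans contacts), so recovery here validates the
implementation and its statistical calibration, not performance on real
Hi-C with its correlated noise, domain hierarchy and normalization
artefacts. Problem sizes (2,000-4,000 bins, 10 null matrices, 100-200
permutation replicates, 600 motifs per group) were chosen as the smallest
that leave Monte-Carlo error well inside the asserted margins.

## Numerical choices and degenerate inputs

Matrix balancing is a damped symmetric Sinkhorn iteration (square-root
update); zero-marginal bins are masked and returned untouched, and
non-convergence warns with the residual. caICB and KR are not
re-implemented — downstream stages only require *a* balanced matrix.
Ties in summit selection break by leftmost anchor; ties at the top-k rank
boundary break by (chromosome, left start, right start). The
directionality index uses truncated windows at chromosome edges and is 0
when upstream and downstream sums are equal (including both zero). All-tied
rank-sum comparisons return p = 1; constant vectors are excluded from
correlation analyses rather than imputed. Entropy of an all-zero profile,
empty groups, empty member lists, and zero-total matrices raise errors.
Floats are serialized with 6 significant digits for reproducible text
diffs; contact files store the upper triangle only and the reader mirrors.

## Known limitations

No spline-based continuous decay fit, per-fragment resolution, trans
contacts, or two-pass refitting; no .hic/cooler binary IO; cross-species
liftover presence analysis is out of scope (requires chain files); GO
content and curated regulator lists are inputs, not reproduced. The
top-10,000 rescue has no principled depth trigger — callers must opt in.
Real-data headline counts (tens of thousands of loops and domains) require
deep genome-wide data and are outside the synthetic benchmark's reach.
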