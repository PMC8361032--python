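# loopdom

CTCF loop domains, topologically isolated genes (TIGs), and boundary
statistics from binned Hi-C contact matrices — with a planted-truth
synthetic benchmark for every stage.

## The problem

Mammalian genomes fold into insulated structures whose boundaries are
CTCF-bound loop anchors. A *CTCF loop domain* is the region delimited by a
significant Hi-C interaction between two CTCF sites; a domain containing
exactly one protein-coding gene (by TSS) topologically isolates that gene
from neighbouring regulatory elements. `loopdom` is for computational
biologists who want to call such domains from binned contact matrices,
classify them by gene content, test whether single-gene domains are more
frequent than chance, and profile their boundaries (virtual-4C contact
strength, sequence conservation, population-variant depletion, enhancer
co-activation) — on their own data or on fully synthetic data with known
ground truth.

## The model

For a chromosome with total contact count N, the expected contact
probability of a bin pair at distance d is estimated on equal-occupancy
distance strata, p̂(d) = contacts/(N·pairs), made monotone by isotonic
regression; each pair is tested with the upper binomial tail
Pr[X ≥ x | n = N, p = p̂(d)] and BH-adjusted across all tested pairs
(significant at q < 0.01, tested range 30 kb–2 Mb by default).
Interactions anchored on CTCF sites at both ends are loops; redundant
loops are merged by a two-step iterative clustering (1 kb anchor window:
50 even/odd-rank preclustering rounds, then complete pairwise merging to
convergence — provably the fixed point of naive repeated merging). Each
domain's working boundaries are the *summit* anchors of its most
significant member loop. Downstream statistics include the permutation
test of the single-gene domain count, the normalized expression entropy
H(x) = −Σ pᵢ ln pᵢ / ln n used to call cell-type-specific regulators,
constitutive domains (present in ≥ 50% of samples), the ROSE-style
slope-1 tangent split of clustered vs typical CTCF sites, and the signed
χ²-like directionality index.

## Worked example

Run the full synthetic benchmark (simulate → call → classify → profile →
score against planted truth):

```sh
loopdom run-all --seed 7 --out-dir out
```

prints

```
domains: {'n_interactions': 275, 'n_loops': 275, 'n_domains': 50, 'median_length': 140000.0,
          'recall': 1.0, 'n_recovered': 50, 'n_called': 50, 'off_truth_fraction': 0.0,
          'max_summit_error_bins': 1}
permutation: {'observed': 50, 'p': 0.001}
virtual4c: {'center_mean': 15.5625, 'center_flank_ratio': 9.688715953307394}
constitutive: {'n_union': 190, 'n_constitutive': 30, 'jaccard_vs_truth': 1.0}
specificity: {'n_called': 50, 'precision': 1.0, 'recall': 1.0}
features: {'conservation_p': 4.83e-67, 'variant_depletion_ratio': 0.1926}
coactivation: {'median_r_within': 0.8127, 'median_r_cross': -0.0330, 'rank_sum_p': 1.05e-99}
```

Reading the numbers: 275 bin pairs reach q < 0.01 and all carry CTCF sites
on both anchors; merging them yields 50 domains whose summits sit within
one bin of all 50 planted loops with no off-truth calls. All 50 domains
hold exactly one planted TSS, and 999 random re-placements of the domains
never reach that count (permutation p = 0.001, the floor). The aggregate
virtual-4C profile peaks at the boundary-to-boundary pixel at ~9.7× the
flank level. The 30 domains shared by all 16 simulated samples are
recovered exactly (Jaccard 1.0) under the ≥ 50% presence rule; the 50
planted low-entropy regulators are called with perfect precision/recall;
boundary motifs show the planted conservation elevation and ~5× variant
depletion (ratio 0.19 vs planted 0.2); and enhancer activity correlates
with its within-domain gene (median r = 0.81) but not with the nearest
cross-domain gene.

Individual stages are available as library functions
(`loopdom.contacts.fit_decay`, `loopdom.domains.call_domains`,
`loopdom.tig.permutation_enrichment`, …) and as CLI subcommands
(`loopdom call`, `classify`, `permtest`, `v4c`, `constitutive`,
`specific`, `enrich`, `simulate`) that read/write BED, BEDPE, bedGraph,
TSV and triplet contact text.

## Layout

- `src/loopdom/genomics.py` — coordinate model, formats IO
- `src/loopdom/contacts.py` — normalization, balancing, decay model,
  significance, directionality index, subtraction maps
- `src/loopdom/domains.py` — CTCF anchoring, two-step merge, summits,
  consensus/constitutive/clustered sites
- `src/loopdom/tig.py` — gene-content classes, shuffling, permutation and
  Fisher tests
- `src/loopdom/virtual4c.py` — boundary-anchored profiles and fold changes
- `src/loopdom/specificity.py` — entropy, specific regulators, enhancers,
  co-activation
- `src/loopdom/features.py` — conservation and variant statistics
- `src/loopdom/simulate.py` — planted-truth generators and scoring
- `src/loopdom/pipeline.py`, `src/loopdom/cli.py` — orchestration and CLI

See `docs/methods.md` for the statistical details, defaults and
limitations.
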