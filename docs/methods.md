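# Methods

## Model overview

The package implements a probabilistic structural equation model over
categorical variables. Both parts — the taxa network that defines the
measurement model and the structural network linking constructs,
covariates and the phenotype — are discrete Bayesian networks with
maximum-likelihood conditional probability tables, learned by score-based
search and queried by exact variable elimination. The assumptions are the
usual ones for discrete BNs: samples are i.i.d. given the graph,
variables are categorical after discretization, and (for the effect
estimates) the fitted joint is treated as the population distribution.

## Preprocessing

Relative abundances are counts over the per-sample total. The editing
filter keeps a genus only if its relative abundance *strictly exceeds*
0.01% in at least one sample of at least one replicate group; surviving
abundances are not renormalized, so downstream log values are unaffected
by the filter. Non-zero abundances are log10-transformed; zeros are not
numbers on that scale and are carried as explicit zero marks that become
a dedicated lowest ordered category. The base (default 10) is
configurable because every downstream step is rank/bin-based.

## Discretization

Both discretizers solve the same 1-D problem — a contiguous partition of
the sorted values minimizing within-bin sum of squares — *exactly*, by
Fisher's dynamic program (vectorized, O(k·n²)). Equivalent genetic or
Lloyd-style optimizers can only approximate this optimum, so the DP is
used as the single optimizer:

* weights: fixed k (default 5), thresholds at midpoints between adjacent
  cluster centers; the seed argument only exists for interface
  stability, since the 1-D optimum is unique up to ties;
* log abundances and construct scores: for each k in {2,…,5} the optimal
  partition is computed and the smallest k whose R² (variance explained
  by bin means) reaches 0.95 is chosen, else the best k. Intervals are
  left-open/right-closed; out-of-range values clamp to the extreme bins.
  Each bin's numeric representative is its training mean; the zero class
  is represented one log-unit below the observed minimum, encoding
  "below detection" as an ordered low value.

## Network learning

The score is the two-part MDL in bits. Per node:
`DL_struct = log2(n)·(1+|parents|) + (log2 N)/2·(arity−1)·Π(parent arities)`,
and `DL_data` is the maximized negative log-likelihood. The structural
coefficient multiplies `DL_struct` only, acting as the complexity dial.
The search is greedy hill-climbing over arc additions, deletions and
reversals with a tabu list, random restarts, a max-parents cap (default
4) and lexicographic tie-breaking, so results are reproducible given the
seed. The score is family-decomposable; a debug mode re-verifies the
decomposability identity at every accepted move. The optional
`sc_scan` learns one network per grid value and flags the arc-count
elbow (largest second difference). The pipeline's default is to adopt
the elbow value: the right sc is a property of the dataset (sample
size and variable arities set the exchange rate between fit and
complexity), not a universal constant, and the elbow reproduces the
intended "sparse but connected" regime on both the N=90 and N=400
generator settings.

Arc strength is the KL arc force: the expectation, under the empirical
distribution, of the log-likelihood ratio between the fitted network and
the network with the arc removed and CPTs refit. Defined this way it
equals the empirical conditional mutual information of parent and child
given the child's other parents, and removing an arc raises the total
description length by exactly N × force. (Taking the expectation under
the model joint instead would break both identities whenever a
v-structure makes the model family marginal differ from the empirical
one.) Significance uses the G-test, G = 2·N·ln2·MI bits, conditioned on
the child's other parents, with p from the chi-square upper tail; arcs
failing the test are flagged rather than removed, and no multiple-testing
correction is applied (a deliberate mirroring of common practice in this
analysis style; a limitation worth remembering at 60 arcs).

## Latent constructs

Clustering is agglomerative, restricted to cluster pairs connected by at
least one skeleton edge, prioritized by average pairwise MI, stopped by
a size cap of ten and an MI floor of 0.02 bits. Each cluster's latent
variable is fitted by EM on the latent-class (naive Bayes) model, best
of several restarts; the latent arity is chosen by a two-part MDL over
{2,3,4} — fewer states than the members' arities, because the latent
exists to summarize, not to memorize. States are relabeled so that
higher states mean higher (MI-weighted) member abundances, making
scores interpretable. Purity is the mean maximum posterior of the
latent state (in percent; the "mean assignment probability" reading of
per-sample MAP confidence). Contingency-table fit is
`100·(H_indep − H_nb)/(H_indep − H_joint)` with H_indep the sum of
member marginal entropies, H_nb the cross-entropy of the data under the
naive-Bayes model and H_joint the empirical joint entropy, clipped to
[0,100]; it is undefined (reported missing) when members are already
independent. Jackknife stability relearns network + clustering on each
of ten subsets and scores each reference cluster by its best-overlap
correspondence (greedy matching; the Hungarian refinement is not needed
at these cluster counts).

## Structural model and effects

The structural table holds ordered categories with numeric
representatives: actual ages in days, weight-class training means in
grams, diet percentages, construct-score bin means. Learning is
bootstrap-aggregated: a tabu-MDL search per resample (default 30–100),
arcs reaching 50% inclusion become priors whose per-arc graph-coding
cost is waived (their parameter cost is kept — otherwise prior arcs
would be free regardless of dimensionality) in the final full-data
search.

The total effect of a source on the target shifts the source's marginal
mean by δ·sd (default δ=0.1) using the exponential tilt — the minimal-KL
soft evidence achieving a given mean — propagates it exactly, and
reports ΔE[target]/ΔE[source] in natural units (grams per unit). The
direct effect is the P(config)-weighted, P(source|config)-weighted
least-squares slope of E[target | source, other parents] on the source
representatives; it is identically zero for non-parents, which makes
"total ≠ 0, direct = 0" an exact mediation signature rather than a
numerical coincidence. Standardized effects multiply by
sd(source)/sd(target) under the fitted joint. Confidence intervals are
percentile bootstrap (rows resampled, CPTs refit, structure fixed);
how the original analysis tool assessed effect significance is not
documented, so the bootstrap is this package's own choice. Inference
uses a 0.5 pseudocount to avoid zero-probability evidence during
propagation; scoring always uses pure MLE to keep MDL semantics.

Cross-validation relearns the structural model per fold and scores
held-out samples by the exact posterior of their weight class given all
other variables; AUC is the Mann–Whitney rank statistic per class,
one-vs-rest, macro-averaged.

## Synthetic generator

`GeneratorSpec` defaults encode the emulated study: 90 samples in three
replicates (each pairing a young cloacal with an older caecal sampling;
diets balanced within replicate), 62 genera in 10 constructs, depth
10,000 reads, age levels {16, 28, 39, 67, 73} days. Constructs are
`α·standardized age + N(0,1)` with α=1 for five of the ten constructs;
taxon log-intensities are `intercept + λ·construct + N(0, 0.6)` with
λ=2, pushed through a softmax and a multinomial at fixed depth, then 20%
independent dropout; weight is `50 + 10.6·age + 35·male + N(0, 60)` g.
Where the emulated design pins a value (sizes, depth, ages, diet
nullity) it is used; free noise scales were fixed once at values
typical for 10k-read 16S data (within-construct pairwise correlations
≈0.6–0.9 after the simplex, zero fractions ≈0.3) and are not tuned per
experiment. The simplex induces negative coupling between constructs —
dominant-genus surges depress everything else — which real relative
abundances also show.

What the generator does *not* emulate: phylogenetic correlation,
abundance-dependent detection (dropout here is independent of
abundance), overdispersion beyond the multinomial, and batch effects.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under a faithful-but-clean data model, not robustness to
every artifact of real sequencing data.

## Known limitations

* **Contingency-table fit under dropout.** With 20% independent dropout
  and N=400, the CTF of recovered constructs plateaus near 50–65% even
  when the latent model is essentially correct (purity ≈95–99%, ARI
  1.0): the dropout component of each member's entropy is genuinely
  unexplainable by any latent, and the plug-in empirical joint entropy
  in the denominator is negatively biased when the member-pattern
  support exceeds the sample size. CTF values on such data should be
  read comparatively, not against absolute thresholds; the 70% rule of
  thumb presumes low-entropy (zero-dominated) members.
* Arc directions within an equivalence class are score-indistinguishable;
  only the skeleton and v-structures are identified, so individual
  directed arcs (e.g. into the phenotype) can flip between seeds.
* Effects are functionals of the fitted joint, not counterfactual
  identification results; they inherit the network's causal reading.
* The G-test p-values are asymptotic and uncorrected for multiplicity.

## Problem sizes

Default analysis sizes — 90×62 end-to-end, N=400 recovery, 20-seed
structure recovery, 10-seed mediation, 30–100 bootstrap resamples, 500
effect bootstraps in the drivers — were chosen so a complete analysis
runs in a few minutes on a single core while keeping every Monte-Carlo
margin comfortable.
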