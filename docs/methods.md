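# Methods

## The question and the model

A strictly vertically transmitted virus should cospeciate with its hosts:
the virus phylogeny, restricted to the sampled host–virus pairs, should be
topologically identical to the host phylogeny. Host switching breaks this
mirror. `cophylo` frames the comparison entirely at the level of unrooted
topologies — branch lengths of host and virus trees live on different scales
(time vs. substitutions at very different rates), and rooting of the virus
tree depends on an outgroup that is excluded from the comparison, so all
three congruence tests operate on the set of non-trivial bipartitions of the
shared leaf set after `map_and_prune`: unmapped (outgroup) taxa are pruned,
mapped virus leaves are relabelled with their host names, and branch lengths
are dropped. Topology comparison is therefore invariant to rerooting of
either tree; this unrooted-after-pruning convention is our documented choice
where the comparison could also have been rooted.

## Likelihood

Sequence evolution is modelled as a reversible continuous-time Markov chain:
GTR exchangeabilities *s*ᵢⱼ (order AC, AG, AT, CG, CT, GT; GT is the
reference), stationary frequencies π, rate matrix *Q*ᵢⱼ = *s*ᵢⱼπⱼ scaled so
−Σπᵢ*Q*ᵢᵢ = 1 (branch lengths in expected substitutions/site). Among-site
rate variation uses the standard k = 4 equal-probability discrete-gamma
(mean-of-category rates via the incomplete-gamma identity); a proportion
p_inv of sites is invariable, and the gamma mean stays 1 when both are
present (the "+Γ+I" convention of the classic tools). Site likelihoods come
from Felsenstein pruning over pattern-compressed columns with per-node
rescaling (log-accumulated) against underflow; transition matrices are
computed by eigendecomposition of the π-symmetrised *Q*. IUPAC ambiguity
codes are partial observations (ones at compatible states); `-`/`N`/`?` are
fully missing. Per-original-column log-likelihood vectors are exposed
because the SH test's RELL resampling needs them.

Correctness anchors: exhaustive summation over internal-node states on all
trees with ≤ 5 leaves (20 random model/tree draws, 1e-8 log units), the JC
closed forms for P(t) and the two-taxon likelihood and branch-length MLE,
invariance to root placement, and exact reduction to the homogeneous model
at p_inv = 0, k = 1.

## Optimization

Branch lengths are optimized coordinate-wise: for each edge the conditional
likelihoods of the two half-trees are computed once and bounded Brent search
runs on the resulting one-dimensional profile (an order of magnitude cheaper
than full re-evaluation per step); sweeps repeat until the total lnL gains
less than 1e-6. Because scipy's bounded Brent bottoms out near √ε·|x|, a
finite-difference Newton polish follows when higher precision is requested.
Model parameters are fitted jointly with log branch lengths by bounded
L-BFGS-B (exchangeabilities and frequency weights in log space, p_inv on its
natural bounded scale), interleaved with branch sweeps. Pure alternation of
model-only and branch-only steps was tried first and converges too slowly
along the strong p_inv/α/tree-length ridge — slowly enough to violate the
nesting guarantee lnL(GTR+Γ+I) ≥ lnL(JC) on JC data; joint optimization
restores it. The gamma shape is bounded in [0.02, 10⁴] so the
equal-rates limit is reachable; its discretisation means α estimates near
the upper bound are indistinguishable from "no rate variation".

The topology search is best-improvement NNI hill climbing from a
neighbor-joining start tree on JC distances (saturation capped at p = 0.70):
all neighbors of all internal edges are scored with the five perturbed
branch lengths re-optimized, the best improving move is accepted and all
branches re-swept, until no move improves; model parameters are re-fitted at
the end. lnL is non-decreasing along the search trace by construction.

AIC model selection fits each candidate family on the fixed topology
(branch lengths re-optimized per candidate), scores AIC = 2K − 2lnL with K
counting branch lengths plus free model parameters, and breaks ties toward
fewer parameters then name, making the choice independent of candidate
order. The default ladder is the 16-member JC/K80/HKY/GTR × {,+Γ,+I,+Γ+I}
set; the classic 56-model ladder adds nothing here because the pipeline only
needs a family, not a named sub-model.

Bootstrap replicates resample columns with replacement and re-analyse each
replicate from its own NJ start tree. Starting replicate searches at the ML
tree (cheaper, and tried first) freezes hill climbing on likelihood
plateaus and inflates the support of unsupported splits to 1.0, so the
fresh-start design is used; 100 replicates by default.

## Bayesian MCMC

A single Metropolis–Hastings chain samples (topology, branch lengths, model
parameters). Proposals (weights in parentheses): uniform NNI on a random
internal edge (3), single-branch multiplier e^{λ(u−½)}, λ = 1 (5), sliding
windows with reflection on α (width 0.4) and p_inv (width 0.1) (1 each), and
Dirichlet proposals (concentration 300) on the frequency and exchangeability
simplices (1 each), with exact Hastings ratios for the multiplier and
Dirichlet moves. Priors: iid exponential (mean 0.1) branch lengths, flat
Dirichlet on π and on the exchangeability simplex, exponential (mean 1) on
α, uniform(0,1) on p_inv. Defaults mirror the classic profile — 10⁶
generations, sampled every 100, first 25% discarded — while desk-scale runs
use 50,000 generations (the CLI default) or less; the retained sample size
is ⌊generations/interval⌋·(1 − burn-in) to within one sample. Convergence is
reported as the maximum split-frequency discrepancy between the two halves
of the retained sample, warning above 0.05. The chain is single (no
Metropolis coupling): at the 8-taxon scale the NNI proposals mix well, and
the congruence tests only consume a topology sample. Validation: the
fixed-topology two-taxon posterior mean matches numerical quadrature of
prior × likelihood; on an empty alignment (flat likelihood) the three
quartet topologies are visited uniformly (chi-square at α = 0.01, with an
inflated bound because thinned samples remain autocorrelated).

## The three congruence tests

**SH test.** The constrained topology rearranges the mapped leaves of the ML
tree into one intact clade mirroring the host topology, attached where the
mapped subtree sat; outgroups keep their ML arrangement. Both candidate
topologies get fresh branch-length and model-parameter optimization on the
same alignment, and identical topologies share one optimized site-likelihood
vector, so a congruent ML tree yields exactly 2ΔlnL = 0, p = 1. RELL
resampling (default 1,000 replicates) draws site columns with replacement;
per-topology replicate sums are centered by their own replicate mean, each
replicate's statistic is the centered maximum minus the topology's centered
value, and p is the fraction of replicates at or above the observed
lnL_best − lnL_topology. With two candidates this reduces to the standard
two-tree SH test but the centering follows the general multi-topology
recipe. The test is conservative by construction, which the type-I
experiment confirms.

**Posterior matching.** Each retained posterior tree is pruned/relabelled
and compared unrooted to the host topology; the statistic is the matching
fraction (with its count). Burn-in must already have been applied.

**RF null.** The posterior's RF distances to the host tree are summarised by
their mean (median available; both always reported, plus a pairwise variant
— the expected fraction of random trees beating a random posterior draw —
because "closer than the posterior sample" admits either reading). The null
is 10⁴ topologies drawn uniformly from the (2n−5)!! labelled unrooted binary
topologies — the maximal-entropy choice absent any stated shape model; the
reported fraction is the share of null draws strictly below the posterior
summary. For seven taxa the null can be enumerated exactly over all 945
topologies, which the Monte-Carlo fraction reproduces within binomial error.

## Synthetic data: what it emulates and what it does not

Host trees are Yule pure-birth: exponential waits with rate k·λ among k
extant lineages, uniform splitting lineage, one extra wait after the n-th
lineage so terminal branches are positive; trees are ultrametric and the
time to grow from 2 to n lineages has mean Σ₂^{n−1} 1/(kλ). The virus tree
is the host tree relabelled and scaled by `virus_rate_scale`, then hit by
`n_switches` random SPR moves — uniformly chosen pruned subtree, uniformly
chosen regraft edge outside it, redrawn until the unrooted topology actually
changes; the freed branch merges into the former sibling edge and the
regraft edge is bisected. Host switches are topology-only events: no timing
model, no extinction, no preferential switching toward related hosts,
because the congruence tests consume topology alone. Alignments evolve site
by site: invariable with probability p_inv (state from π), otherwise a
uniform gamma category, root state from π, transitions by exp(Qtr) down the
tree.

The packaged study conditions are 8 hosts, Yule rate 1, virus rate scale 0.5
(sigma-virus RDRP data are highly divergent — the closest real pair sits
near 0.73 amino-acid identity — and 0.5 substitutions/site per host-time
unit reproduces that JC-distance range), alignment length 2,000 nt, GTR+Γ+I
with transition bias 4, π = (0.32, 0.17, 0.22, 0.29), α = 0.5, p_inv = 0.1,
scenario seed 101; the two fixtures differ only in 0 vs 3 switches. What
passing tests on these data do **not** show: robustness to alignment error
or trimming choices, to substitution saturation beyond the simulated depth,
to model misspecification (the analysis model family contains the
generating model), or to rate variation across virus lineages
(`rate_noise_sd` exists but defaults to off).

## Problem sizes and numerical choices

Desk-scale experiment sizes — 40 cospeciation replicates for type-I, 20
three-switch replicates for power (10 each in the acceptance script), 50,000
MCMC generations for the packaged fixtures and 10,000 for power replicates —
were chosen so the whole battery runs in minutes on one CPU while leaving
the binomial bounds meaningful. Branch lengths live in [1e-8, 20];
optimizer tolerance 1e-6 lnL; RELL ≥ 100 replicates enforced; ties in AIC
break toward parsimony; degenerate inputs (trees under 4 leaves, empty
posteriors, non-injective associations, mismatched leaf sets) raise typed
errors naming the offending taxa. Reported lnL values are finite by
construction; a non-finite posterior aborts the MCMC with diagnostic state
rather than continuing.

## Known limitations

The packaged cospeciation world is not perfectly resolvable: its Yule draw
places one short deep edge (~0.16 substitutions/site) next to the very long
first-host branch, and both the Bayesian posterior (split support ~0.84 from
converged chains) and the ML bootstrap (0.78) agree that 2,000 sites leave
that split uncertain. The posterior match proportion on this fixture
therefore converges near 0.87 rather than 1 — a property of the drawn
scenario that the error-rate drivers report as-is.

NNI-only search can stop at local optima that SPR/TBR would escape (observed
as occasional near-tie alternative topologies on switch fixtures; harmless
to the congruence statistics, which re-optimize whatever tree is supplied).
The SH test's conservatism means its type-I rate sits well below nominal α.
The RF null's uniform-topology assumption makes the "2%-style" residual
similarity statistic conservative against Yule-shaped alternatives (a
Yule-null option would sharpen it). Amino-acid and codon models, partitioned
analyses, divergence dating and event-based cophylogeny reconciliation are
out of scope.
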