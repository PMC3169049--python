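# cophylo — host–virus phylogenetic congruence testing

Vertically transmitted symbionts — here, sigma viruses, the CO₂-paralysis
rhabdoviruses of *Drosophila* and other flies — are inherited through eggs
and sperm, so under strict host-fidelity their phylogeny should mirror their
hosts' phylogeny (cospeciation). `cophylo` implements the statistical
machinery for asking whether a virus phylogeny actually tracks its hosts or
whether the viruses have switched between host lineages, for researchers who
have a virus gene alignment (e.g. a conserved region of the RNA-dependent
RNA polymerase), a well-resolved host tree, and a virus→host association.

The package provides, as a tested pipeline:

* **Phylogenetic likelihood** under GTR+Γ+I — Felsenstein pruning with
  4-category discrete-gamma rate variation and a proportion of invariable
  sites, on pattern-compressed alignments;
* **ML inference** — branch-length and model-parameter optimization, NNI
  hill-climbing tree search from a neighbor-joining start, AIC model
  selection over the JC/K80/HKY/GTR ± Γ ± I ladder, nonparametric bootstrap;
* **Bayesian inference** — single-chain Metropolis–Hastings over topology,
  branch lengths and model parameters (the classic profile: 10⁶ generations,
  sampled every 100, 25% burn-in);
* **Three congruence tests**:
  1. **SH test** — 2ΔlnL between the ML virus tree and a tree constrained to
     mirror the host topology, with RELL resampling p-values;
  2. **posterior matching** — the proportion of posterior virus topologies
     identical (unrooted, after pruning to mapped taxa) to the host topology;
  3. **RF null** — the fraction of 10⁴ uniformly random topologies whose
     Robinson–Foulds distance to the host tree is smaller than the
     posterior's summary distance, a test of residual similarity even when
     the trees are incongruent;
* **A synthetic cophylogeny simulator** — Yule host trees, virus trees with
  a configurable number of host-switch (SPR) events, and sequence evolution
  under GTR+Γ+I — so both error rates of every test are measurable without
  external data.

## Worked example

Simulate a world in which the virus switched hosts three times, then test
for congruence:

```bash
cophylo simulate --n-hosts 8 --n-switches 3 --length 2000 --seed 7 --outdir demo
cophylo congruence \
    --alignment demo/alignment.fasta --host-tree demo/host.nwk \
    --association demo/association.tsv \
    --generations 10000 --sample-every 50 --n-random 2000 \
    --seed 4 --outdir demo/out
```

prints

```
SH test: 2*dlnL = 39.9, p = 0.005
posterior match: 0/150 (0.000)
RF null (mean): fraction of random topologies closer than the posterior = 0.0375
```

Read: the likelihood of the virus tree drops significantly when forced onto
the host topology (SH rejects congruence), no posterior virus topology
matches the host tree — both diagnostic of host switching — and yet only
~4% of random topologies are closer to the host tree than the posterior is,
so the virus tree still resembles its hosts' more than chance would allow
(the unswitched part of the shared history). `--paper-profile` swaps in the
full-scale MCMC settings (10⁶ generations, sampled every 100, 25% burn-in).
With a cospeciation fixture (`--n-switches 0`) the same battery returns
2ΔlnL = 0, p = 1 and a posterior match proportion near 1.

The numbered scripts under `analysis/` run the same battery as a narrative
pipeline (fixtures → ML → MCMC → congruence tests → error rates), writing
tables under `results/`.

An externally produced posterior (MrBayes `.t` trees block with a Translate
table) can be supplied via `--posterior`, mirroring the
infer-with-MrBayes-then-test workflow. For the sigma-virus data themselves,
fetch the RDRP accessions printed as JF311399–JF211402 (the range as
printed; JF311399–JF311402 in sequential reading) from GenBank, e.g.
`efetch -db nucleotide -id JF311399 -format fasta`, align, trim to the
conserved RDRP region, and pass the alignment to `cophylo congruence`.

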