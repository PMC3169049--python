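"""Host-virus topological congruence tests.

Three complementary tests of whether a virus phylogeny tracks its hosts'
phylogeny, as used to demonstrate host switching in vertically transmitted
sigma viruses:

1. **SH test** — compare the likelihood of the unconstrained ML virus tree
   with a tree constrained to mirror the host topology; significance by RELL
   resampling of per-site log-likelihoods.
2. **Posterior matching** — the proportion of a Bayesian posterior sample of
   virus topologies that equal the host topology (after pruning to the
   mapped taxa; comparison is unrooted).
3. **RF null** — is the posterior closer to the host topology than random
   trees are?  The fraction of uniformly random topologies whose
   Robinson-Foulds distance to the host tree is smaller than the posterior
   summary (mean by default, median optional) measures residual topological
   similarity even when the trees are incongruent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .alignment import Alignment
from .inference import (
    DEFAULT_CANDIDATES,
    aic_select,
    default_model,
    ml_search,
    optimize_model_parameters,
    starting_tree,
)
from .likelihood import PruningEngine
from .mcmc import MCMCConfig, mcmc_sample
from .model import SubstitutionModel
from .posterior import PosteriorSample
from .tree import (
    HostAssociation,
    Node,
    PhyloTree,
    TreeError,
    map_and_prune,
    random_topology,
    rf_distance,
    topologies_equal,
)

__all__ = [
    "CongruenceConfig",
    "CongruenceReport",
    "SHResult",
    "MatchResult",
    "RFNullResult",
    "build_constrained_tree",
    "sh_test",
    "rell_sh_pvalues",
    "posterior_match_proportion",
    "rf_null_test",
    "run_congruence_suite",
]


# ---------------------------------------------------------------------------
# Constrained topology construction
# ---------------------------------------------------------------------------

def _host_clade_with_virus_labels(
    host_tree: PhyloTree, assoc: HostAssociation
) -> Node:
    """The host topology on the mapped hosts, relabelled with virus taxa."""
    hosts = assoc.host_taxa
    missing = sorted(hosts - host_tree.leaf_names())
    if missing:
        raise TreeError(f"host tree missing mapped host taxa: {missing}")
    virus_of = {h: v for v, h in assoc.items()}
    work = host_tree.copy()
    drop = work.leaf_names() - hosts
    if drop:
        from .tree import _prune_leaves

        _prune_leaves(work, set(drop))
    for leaf in work.leaves():
        leaf.name = virus_of[leaf.name]
    work.drop_lengths()
    return work.root


def build_constrained_tree(
    ml_tree: PhyloTree, host_tree: PhyloTree, assoc: HostAssociation
) -> PhyloTree:
    """A virus tree whose induced topology on the mapped taxa is the host's.

    The mapped leaves are rearranged to mirror the host topology as one
    intact clade attached where the mapped subtree sat in ``ml_tree``;
    unmapped (outgroup) taxa keep their ML arrangement.  Branch lengths are
    dropped — the caller re-optimizes them.  By construction,
    ``map_and_prune(result, assoc)`` equals the host topology.
    """
    leaves = ml_tree.leaf_names()
    mapped = assoc.virus_taxa
    missing = sorted(mapped - leaves)
    if missing:
        raise TreeError(f"mapped virus taxa absent from ML tree: {missing}")
    clade = _host_clade_with_virus_labels(host_tree, assoc)
    if mapped == leaves:
        return PhyloTree(clade)

    outgroup = sorted(leaves - mapped)
    work = ml_tree.rerooted_at(outgroup[0])

    def ancestors(n: Node) -> List[Node]:
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    def mrca(nodes: List[Node]) -> Node:
        cur = nodes[0]
        common = {id(a) for a in ancestors(cur)}
        for other in nodes[1:]:
            n = other
            while id(n) not in common:
                n = n.parent
            cur = n
            common = {id(a) for a in ancestors(cur)}
        return cur

    m = mrca([work.find_leaf(v) for v in sorted(mapped)])
    # nearest point with unmapped descendants: the attachment context W
    probe = m
    while True:
        unmapped_below = {l.name for l in probe.leaves()} - mapped
        if unmapped_below or probe.parent is None:
            break
        probe = probe.parent
    W = frozenset(unmapped_below) if unmapped_below else frozenset(outgroup)

    from .tree import _prune_leaves

    _prune_leaves(work, set(mapped))
    work.drop_lengths()
    # attach the clade on the edge above the W subtree
    target = None
    for node in work.postorder():
        if frozenset(l.name for l in node.leaves()) == W and node.parent is not None:
            target = node
            break
    if target is None:  # W is the whole remaining tree: attach at the root
        new_root = Node()
        new_root.add_child(work.root)
        new_root.add_child(clade)
        return PhyloTree(new_root)
    parent = target.parent
    mid = Node()
    parent.children[parent.children.index(target)] = mid
    mid.parent = parent
    mid.add_child(target)
    mid.add_child(clade)
    return PhyloTree(work.root)


# ---------------------------------------------------------------------------
# SH test with RELL resampling
# ---------------------------------------------------------------------------

@dataclass
class SHResult:
    """Shimodaira-Hasegawa test outcome for the constrained topology."""

    delta2: float          # 2 * (lnL_best - lnL_constrained)
    p_value: float
    lnL: List[float]       # per input topology, same order
    p_values: List[float]  # per input topology
    n_rell: int
    seed: int


def rell_sh_pvalues(
    site_loglik: Sequence[np.ndarray], n_rell: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """SH p-values from per-site log-likelihood vectors by RELL resampling.

    For each topology t the observed statistic is ``lnL_best - lnL_t``.
    Replicates resample site columns with replacement; per-topology replicate
    sums are centered by their own replicate mean, and each replicate's
    statistic is the centered maximum over topologies minus the topology's
    centered value.  ``p_t`` is the fraction of replicates at or above the
    observed statistic.  Returns (deltas, p_values).
    """
    S = np.vstack([np.asarray(v, float) for v in site_loglik])  # (T, L)
    T, L = S.shape
    totals = S.sum(axis=1)
    deltas = totals.max() - totals
    rng = np.random.default_rng(seed)
    R = np.empty((T, n_rell))
    # resample in blocks to bound memory
    block = max(1, min(n_rell, int(2e6 // max(L, 1)) or 1))
    done = 0
    while done < n_rell:
        b = min(block, n_rell - done)
        idx = rng.integers(L, size=(b, L))
        for t in range(T):
            R[t, done:done + b] = S[t][idx].sum(axis=1)
        done += b
    Rc = R - R.mean(axis=1, keepdims=True)
    D = Rc.max(axis=0)[None, :] - Rc
    p = (D >= deltas[:, None] - 1e-12).mean(axis=1)
    return deltas, p


def sh_test(
    aln: Alignment,
    model: SubstitutionModel,
    topologies: Sequence[PhyloTree],
    n_rell: int = 1000,
    seed: int = 0,
    refit_model: bool = True,
    model_rounds: int = 1,
) -> SHResult:
    """SH test of candidate topologies (ML tree first, constrained second).

    Branch lengths — and, with ``refit_model``, the model parameters of
    ``model``'s family — are re-optimized per topology on the same alignment
    before the per-site log-likelihoods enter the RELL resampling.
    ``delta2``/``p_value`` report the *last* topology (the constrained one by
    convention); identical topologies give delta2 = 0, p = 1.
    """
    if n_rell < 100:
        raise ValueError(f"n_rell must be >= 100, got {n_rell}")
    leafsets = {t.leaf_names() for t in topologies}
    if len(leafsets) != 1:
        raise TreeError("SH test topologies must share one taxon set")
    engine = PruningEngine(aln, taxa=sorted(topologies[0].leaf_names()))
    site_vectors = []
    for topo in topologies:
        same = next(
            (
                j
                for j, prev in enumerate(topologies[: len(site_vectors)])
                if topologies_equal(topo, prev)
            ),
            None,
        )
        if same is not None:
            # identical topologies share one optimized site-likelihood vector
            site_vectors.append(site_vectors[same])
            continue
        if refit_model:
            tree, m, _ = optimize_model_parameters(
                topo, aln, model, family=model.name, rounds=model_rounds, engine=engine
            )
        else:
            from .inference import optimize_branch_lengths

            tree, _ = optimize_branch_lengths(topo, aln, model, engine=engine)
            m = model
        site_vectors.append(engine.site_log_likelihoods(tree, m).values)
    deltas, p = rell_sh_pvalues(site_vectors, n_rell, seed)
    return SHResult(
        delta2=float(2.0 * deltas[-1]),
        p_value=float(p[-1]),
        lnL=[float(v.sum()) for v in site_vectors],
        p_values=[float(x) for x in p],
        n_rell=n_rell,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Posterior topology matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    proportion: float
    count: int
    n: int


def posterior_match_proportion(
    sample: PosteriorSample, host_tree: PhyloTree, assoc: HostAssociation
) -> MatchResult:
    """Fraction of posterior virus topologies equal to the host topology.

    Each sampled tree is pruned to the mapped taxa, relabelled with host
    names and compared unrooted; rerooting of either tree cannot change the
    result.  Expects burn-in to have been applied already.
    """
    if len(sample) == 0:
        raise ValueError("empty posterior sample")
    host = _pruned_host(host_tree, assoc)
    count = sum(
        topologies_equal(map_and_prune(t, assoc), host) for t in sample.trees
    )
    return MatchResult(proportion=count / len(sample), count=count, n=len(sample))


def _pruned_host(host_tree: PhyloTree, assoc: HostAssociation) -> PhyloTree:
    hosts = assoc.host_taxa
    missing = sorted(hosts - host_tree.leaf_names())
    if missing:
        raise TreeError(f"host tree missing mapped host taxa: {missing}")
    work = host_tree.copy()
    drop = work.leaf_names() - hosts
    if drop:
        from .tree import _prune_leaves

        _prune_leaves(work, set(drop))
    work.drop_lengths()
    return work


# ---------------------------------------------------------------------------
# Robinson-Foulds random-topology null
# ---------------------------------------------------------------------------

@dataclass
class RFNullResult:
    """RF distances of posterior and random topologies to the host tree.

    ``fraction`` is the share of random topologies strictly closer to the
    host than the posterior summary distance ``d_star`` (mean over the
    posterior by default; the median variant and a pairwise variant —
    the expected fraction of random trees beating a random posterior draw —
    are always reported alongside).
    """

    fraction: float
    d_star: float
    summary: str
    fraction_mean: float
    fraction_median: float
    fraction_pairwise: float
    posterior_rf: List[int]
    null_rf: List[int]
    n_random: int
    seed: int


def rf_null_test(
    sample: PosteriorSample,
    host_tree: PhyloTree,
    assoc: HostAssociation,
    n_random: int = 10_000,
    summary: str = "mean",
    seed: int = 0,
) -> RFNullResult:
    """Compare posterior RF distances to the host against a uniform null.

    Draws ``n_random`` uniformly random unrooted binary topologies on the
    host leaf set, computes their RF distances to the host topology, and
    reports the fraction that fall strictly below the posterior summary
    distance.
    """
    if len(sample) == 0:
        raise ValueError("empty posterior sample")
    if n_random < 100:
        raise ValueError(f"n_random must be >= 100, got {n_random}")
    if summary not in ("mean", "median"):
        raise ValueError(f"summary must be 'mean' or 'median', got {summary!r}")
    host = _pruned_host(host_tree, assoc)
    post = [rf_distance(host, map_and_prune(t, assoc)) for t in sample.trees]
    rng = np.random.default_rng(seed)
    taxa = sorted(host.leaf_names())
    null = [
        rf_distance(host, random_topology(taxa, rng)) for _ in range(n_random)
    ]
    null_arr = np.asarray(null)
    d_mean = float(np.mean(post))
    d_median = float(np.median(post))
    frac_mean = float(np.mean(null_arr < d_mean))
    frac_median = float(np.mean(null_arr < d_median))
    null_sorted = np.sort(null_arr)
    frac_pairwise = float(
        np.mean(np.searchsorted(null_sorted, np.asarray(post), side="left") / n_random)
    )
    d_star = d_mean if summary == "mean" else d_median
    return RFNullResult(
        fraction=frac_mean if summary == "mean" else frac_median,
        d_star=d_star,
        summary=summary,
        fraction_mean=frac_mean,
        fraction_median=frac_median,
        fraction_pairwise=frac_pairwise,
        posterior_rf=[int(x) for x in post],
        null_rf=[int(x) for x in null],
        n_random=n_random,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Full suite
# ---------------------------------------------------------------------------

@dataclass
class CongruenceConfig:
    """Settings for the end-to-end congruence analysis."""

    candidates: Sequence[str] = ("GTR+G+I",)
    n_rell: int = 1000
    n_random: int = 10_000
    summary: str = "mean"
    seed: int = 0
    mcmc: MCMCConfig = field(default_factory=lambda: MCMCConfig(
        generations=50_000, sample_interval=100, burnin_fraction=0.25
    ))
    posterior: Optional[PosteriorSample] = None  # external sample, burn-in pending
    burnin_fraction: float = 0.25  # applied to an external posterior


@dataclass
class CongruenceReport:
    """All three congruence statistics with their settings and seeds."""

    sh_delta: float
    sh_p: float
    match_proportion: float
    match_count: int
    posterior_size: int
    rf_null_fraction: float
    rf_null_fraction_mean: float
    rf_null_fraction_median: float
    rf_null_fraction_pairwise: float
    rf_summary: str
    posterior_rf_distribution: List[int]
    null_rf_distribution: List[int]
    settings: Dict[str, object]
    selected_model: str = ""
    ml_lnL: float = 0.0
    constrained_lnL: float = 0.0

    SCALARS = (
        "sh_delta", "sh_p", "match_proportion", "match_count", "posterior_size",
        "rf_null_fraction", "rf_null_fraction_mean", "rf_null_fraction_median",
        "rf_null_fraction_pairwise", "ml_lnL", "constrained_lnL",
    )

    def to_text(self) -> str:
        lines = ["# host-virus congruence report"]
        for key in self.SCALARS:
            lines.append(f"{key}: {getattr(self, key)!r}")
        lines.append(f"rf_summary: {self.rf_summary!r}")
        lines.append(f"selected_model: {self.selected_model!r}")
        lines.append(f"settings: {self.settings!r}")
        lines.append(
            "posterior_rf_distribution: "
            + ",".join(str(x) for x in self.posterior_rf_distribution)
        )
        lines.append(
            "null_rf_distribution: " + ",".join(str(x) for x in self.null_rf_distribution)
        )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CongruenceReport":
        import ast

        data: Dict[str, object] = {}
        for line in text.splitlines():
            if line.startswith("#") or ":" not in line:
                continue
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key in ("posterior_rf_distribution", "null_rf_distribution"):
                data[key] = [int(x) for x in value.split(",")] if value else []
            else:
                data[key] = ast.literal_eval(value)
        return cls(**data)  # type: ignore[arg-type]

    def summary_text(self) -> str:
        return (
            f"SH test: 2*dlnL = {self.sh_delta:.1f}, p = {self.sh_p:.4g}\n"
            f"posterior match: {self.match_count}/{self.posterior_size} "
            f"({self.match_proportion:.3f})\n"
            f"RF null ({self.rf_summary}): fraction of random topologies closer "
            f"than the posterior = {self.rf_null_fraction:.4g}"
        )


def run_congruence_suite(
    aln: Alignment,
    host_tree: PhyloTree,
    assoc: HostAssociation,
    config: Optional[CongruenceConfig] = None,
    capture: Optional[Dict[str, object]] = None,
) -> CongruenceReport:
    """Run the full battery: model selection + ML + SH, MCMC + matching + RF null.

    Stages: AIC model selection on a distance start tree, NNI ML search under
    the selected family, host-constrained tree construction and SH test;
    Bayesian MCMC (or an externally supplied posterior) for the posterior
    match proportion and the RF random-topology null.  All seeds and settings
    are recorded in the returned report.
    """
    config = config or CongruenceConfig()
    seed = config.seed

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"congruence stage '{name}' failed: {exc}") from exc

    start = stage("start-tree", starting_tree, aln)
    if len(config.candidates) > 1:
        sel = stage("model-selection", aic_select, aln, start, config.candidates)
        family = sel.selected
    else:
        family = config.candidates[0]
    ml = stage("ml-search", ml_search, aln, family, start, seed)
    constrained = stage(
        "constrained-tree", build_constrained_tree, ml.tree, host_tree, assoc
    )
    sh = stage(
        "sh-test", sh_test, aln, ml.model, [ml.tree, constrained],
        config.n_rell, seed,
    )
    if config.posterior is not None:
        posterior = config.posterior.without_burnin(config.burnin_fraction)
    else:
        mcmc_cfg = config.mcmc
        mcmc_cfg = MCMCConfig(**{**asdict_config(mcmc_cfg), "seed": seed + 1})
        posterior = stage("mcmc", mcmc_sample, aln, family, mcmc_cfg, start)
    match = stage("posterior-match", posterior_match_proportion, posterior, host_tree, assoc)
    if capture is not None:
        capture.update(ml=ml, constrained=constrained, posterior=posterior, sh=sh)
    rf = stage(
        "rf-null", rf_null_test, posterior, host_tree, assoc,
        config.n_random, config.summary, seed + 2,
    )
    return CongruenceReport(
        sh_delta=sh.delta2,
        sh_p=sh.p_value,
        match_proportion=match.proportion,
        match_count=match.count,
        posterior_size=match.n,
        rf_null_fraction=rf.fraction,
        rf_null_fraction_mean=rf.fraction_mean,
        rf_null_fraction_median=rf.fraction_median,
        rf_null_fraction_pairwise=rf.fraction_pairwise,
        rf_summary=rf.summary,
        posterior_rf_distribution=rf.posterior_rf,
        null_rf_distribution=rf.null_rf,
        settings={
            "seed": seed,
            "n_rell": config.n_rell,
            "n_random": config.n_random,
            "summary": config.summary,
            "candidates": list(config.candidates),
            "mcmc": asdict_config(config.mcmc) if config.posterior is None else "external",
        },
        selected_model=family,
        ml_lnL=sh.lnL[0],
        constrained_lnL=sh.lnL[-1],
    )


def asdict_config(cfg: MCMCConfig) -> Dict[str, object]:
    from dataclasses import asdict

    return asdict(cfg)
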