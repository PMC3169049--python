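"""Synthetic cophylogeny and sequence simulation.

Generates the study conditions every pipeline stage is tested against:

* a **Yule host tree** (pure birth, exponential waiting times, ultrametric);
* a **virus tree** that starts as a relabelled, rate-scaled copy of the host
  tree (strict codivergence) and then suffers a configurable number of
  host-switch events, each modelled as a topology-changing random SPR move;
* a **nucleotide alignment** evolved along the virus tree under GTR+G+I.

With ``n_switches = 0`` the virus topology equals the host topology exactly,
so both error rates of every congruence test are measurable: cospeciation
scenarios estimate type-I error, switch scenarios estimate power.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .alignment import Alignment
from .io import write_association, write_fasta
from .model import (
    SubstitutionModel,
    build_rate_matrix,
    gtr,
    rate_matrix_eigen,
)
from .tree import (
    HostAssociation,
    Node,
    PhyloTree,
    TreeError,
    spr_move,
    write_newick,
)

__all__ = [
    "CophylogenyScenario",
    "FixtureBundle",
    "simulate_host_tree",
    "simulate_virus_tree",
    "simulate_alignment",
    "make_bundle",
    "make_fixture",
    "virus_name",
    "COSPECIATION_8TAXA",
    "SWITCH3_8TAXA",
    "FIXTURE_MODEL",
    "FIXTURE_LENGTH",
]


@dataclass(frozen=True)
class CophylogenyScenario:
    """Parameters of one host-virus co-evolution scenario.

    ``virus_rate_scale`` converts host branch lengths (time units) into
    expected substitutions per site on the virus tree; sigma-virus-like data
    are highly divergent, hence the default of 0.5 substitutions/site per
    unit of host-tree time.  ``rate_noise_sd``, when positive, multiplies
    each virus branch by an independent lognormal factor (mean 1).
    """

    n_hosts: int = 8
    yule_rate: float = 1.0
    n_switches: int = 0
    virus_rate_scale: float = 0.5
    rate_noise_sd: float = 0.0
    seed: int = 101

    def __post_init__(self):
        if self.n_switches < 0:
            raise ValueError("n_switches must be >= 0")
        if self.n_hosts >= 3 and self.n_switches > self.n_hosts - 3:
            raise ValueError(
                f"n_switches must be <= n_hosts - 3 "
                f"({self.n_switches} > {self.n_hosts - 3})"
            )


def virus_name(host: str) -> str:
    return f"v_{host}"


def simulate_host_tree(
    n: int, yule_rate: float = 1.0, seed: Union[int, np.random.Generator] = 0
) -> PhyloTree:
    """An ultrametric Yule (pure-birth) tree on taxa H1..Hn.

    Starting from two lineages, waiting times between speciations are
    exponential with rate ``k * yule_rate`` while ``k`` lineages are extant
    and the splitting lineage is chosen uniformly.  After the n-th lineage
    appears one further exponential wait extends all tips, so terminal
    branches are positive and the tree stays ultrametric.
    """
    if n < 3:
        raise TreeError(f"need at least 3 host taxa, got {n}")
    if yule_rate <= 0:
        raise ValueError("yule_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = Node()
    active: list[Tuple[Node, float]] = []
    for _ in range(2):
        child = root.add_child(Node())
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * yule_rate))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.length = t - born
        for _ in range(2):
            child = node.add_child(Node())
            active.append((child, t))
    t += rng.exponential(1.0 / (n * yule_rate))
    for node, born in active:
        node.length = t - born
    for i, leaf in enumerate(root.leaves(), 1):
        leaf.name = f"H{i}"
    return PhyloTree(root)


def simulate_virus_tree(
    host_tree: PhyloTree,
    scenario: CophylogenyScenario,
    rng: Optional[np.random.Generator] = None,
) -> PhyloTree:
    """The virus tree implied by codivergence plus ``n_switches`` host switches.

    The host tree is copied, leaves renamed ``H`` -> ``v_H``, branch lengths
    multiplied by ``virus_rate_scale`` (and optional lognormal noise), then
    ``n_switches`` random SPR moves are applied, each guaranteed to change
    the unrooted topology.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    n = host_tree.n_leaves
    if scenario.n_switches > n - 3:
        raise TreeError(
            f"n_switches must be <= n_hosts - 3 ({scenario.n_switches} > {n - 3})"
        )
    tree = host_tree.copy()
    for leaf in tree.leaves():
        leaf.name = virus_name(leaf.name)
    for node in tree.edges():
        node.length = node.length * scenario.virus_rate_scale
        if scenario.rate_noise_sd > 0:
            sd = scenario.rate_noise_sd
            node.length *= float(
                np.exp(rng.normal(-0.5 * sd * sd, sd))
            )
    tree = PhyloTree(tree.root)
    for _ in range(scenario.n_switches):
        tree = spr_move(tree, rng, require_change=True)
    return tree


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    L: int,
    seed: Union[int, np.random.Generator] = 0,
) -> Alignment:
    """Evolve ``L`` sites down ``tree`` under ``model``.

    Per site: invariable with probability ``p_inv`` (state drawn from pi,
    constant across the tree), otherwise a uniformly drawn gamma category;
    the root state comes from pi and each branch applies ``exp(Q t r)``.
    """
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    if not tree.has_branch_lengths():
        raise TreeError("tree must have branch lengths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = model.pi
    Q = build_rate_matrix(model)
    w, U, U_inv = rate_matrix_eigen(Q, pi)
    rates = model.category_rates()
    k = len(rates)

    invariable = rng.random(L) < model.p_inv
    category = rng.integers(k, size=L)
    states = np.empty(L, dtype=np.int64)
    states[:] = rng.choice(4, size=L, p=pi)

    state_of: Dict[int, np.ndarray] = {id(tree.root): states}
    nodes = [n for n in tree.postorder()]
    leaf_states: Dict[str, np.ndarray] = {}
    for node in reversed(nodes):  # preorder
        if node.parent is None:
            continue
        parent_states = state_of[id(node.parent)]
        child = parent_states.copy()
        for c in range(k):
            sel = (~invariable) & (category == c)
            if not np.any(sel):
                continue
            P = (U * np.exp(w * node.length * rates[c])[None, :]) @ U_inv
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            u = rng.random(int(sel.sum()))
            ps = parent_states[sel]
            child[sel] = (u[:, None] > cum[ps]).sum(axis=1)
        state_of[id(node)] = child
        if node.is_leaf:
            leaf_states[node.name] = child
    chars = np.array(list("ACGT"))
    return Alignment(
        [(name, "".join(chars[s])) for name, s in sorted(leaf_states.items())]
    )


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """One synthetic dataset: trees, alignment, association, provenance."""

    host_tree: PhyloTree
    virus_tree: PhyloTree
    alignment: Alignment
    association: HostAssociation
    scenario: CophylogenyScenario
    model: SubstitutionModel
    L: int


# the two packaged study conditions: strict codivergence vs three switches
FIXTURE_MODEL = gtr(
    exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
    base_frequencies=(0.32, 0.17, 0.22, 0.29),
    gamma_shape=0.5,
    p_inv=0.1,
).with_(name="GTR+G+I")
FIXTURE_LENGTH = 2000
COSPECIATION_8TAXA = CophylogenyScenario(n_hosts=8, n_switches=0, seed=101)
SWITCH3_8TAXA = CophylogenyScenario(n_hosts=8, n_switches=3, seed=101)


def make_bundle(
    scenario: CophylogenyScenario,
    model: SubstitutionModel = FIXTURE_MODEL,
    L: int = FIXTURE_LENGTH,
) -> FixtureBundle:
    """Generate a complete in-memory fixture for one scenario (deterministic)."""
    rng = np.random.default_rng(scenario.seed)
    host = simulate_host_tree(scenario.n_hosts, scenario.yule_rate, rng)
    virus = simulate_virus_tree(host, scenario, rng)
    aln = simulate_alignment(virus, model, L, rng)
    assoc = HostAssociation(
        {virus_name(h): h for h in sorted(host.leaf_names())}
    )
    return FixtureBundle(
        host_tree=host, virus_tree=virus, alignment=aln,
        association=assoc, scenario=scenario, model=model, L=L,
    )


def make_fixture(
    scenario: CophylogenyScenario,
    model: SubstitutionModel = FIXTURE_MODEL,
    L: int = FIXTURE_LENGTH,
    outdir: Union[str, Path] = ".",
) -> FixtureBundle:
    """Write a fixture to disk: host/virus Newick, FASTA, TSV, provenance.

    Re-invocation with the same scenario and seed reproduces byte-identical
    files.
    """
    outdir = Path(outdir)
    if not outdir.exists():
        raise FileNotFoundError(f"output directory does not exist: {outdir}")
    bundle = make_bundle(scenario, model, L)
    (outdir / "host.nwk").write_text(write_newick(bundle.host_tree) + "\n")
    (outdir / "virus_true.nwk").write_text(write_newick(bundle.virus_tree) + "\n")
    write_fasta(bundle.alignment, outdir / "alignment.fasta")
    write_association(bundle.association, outdir / "association.tsv")
    prov = ["# fixture provenance"]
    for key, val in asdict(scenario).items():
        prov.append(f"scenario.{key}: {val}")
    prov.append(f"alignment_length: {L}")
    prov.append(f"model: {bundle.model.describe()}")
    (outdir / "provenance.txt").write_text("\n".join(prov) + "\n")
    return bundle
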