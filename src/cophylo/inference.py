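"""Maximum-likelihood tree inference.

Covers branch-length optimization (coordinate-wise Brent over edge-profile
likelihoods), substitution-model parameter optimization (bounded quasi-Newton
interleaved with branch sweeps), the NNI hill-climbing topology search with a
neighbor-joining start tree, AIC model selection over the JC/K80/HKY/GTR
ladder, and nonparametric bootstrap support.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import Alignment
from .likelihood import PruningEngine
from .model import SubstitutionModel, gtr, hky, jc, k80
from .tree import (
    Node,
    PhyloTree,
    TreeError,
    _find_edge_node,
    _reroot_at_node,
    bipartition_set,
    internal_edges,
    parse_newick,
)

__all__ = [
    "MLResult",
    "ModelSelectionResult",
    "parse_family",
    "family_name",
    "n_free_model_parameters",
    "default_model",
    "starting_tree",
    "optimize_branch_lengths",
    "optimize_model_parameters",
    "ml_search",
    "aic_select",
    "bootstrap_support",
    "DEFAULT_CANDIDATES",
]

MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------

DEFAULT_CANDIDATES: Tuple[str, ...] = tuple(
    base + suffix
    for base in ("JC", "K80", "HKY", "GTR")
    for suffix in ("", "+G", "+I", "+G+I")
)


def parse_family(name: str) -> Tuple[str, bool, bool]:
    """Split a family name like ``"GTR+G+I"`` into (base, gamma?, inv?)."""
    parts = name.upper().replace(" ", "").split("+")
    base = parts[0]
    if base not in ("JC", "K80", "HKY", "GTR"):
        raise ValueError(f"unknown model family base: {name!r}")
    flags = set(parts[1:])
    bad = flags - {"G", "I"}
    if bad:
        raise ValueError(f"unknown model suffix {sorted(bad)} in {name!r}")
    return base, "G" in flags, "I" in flags


def family_name(base: str, gamma: bool, inv: bool) -> str:
    return base + ("+G" if gamma else "") + ("+I" if inv else "")


def n_free_model_parameters(family: str) -> int:
    base, gamma, inv = parse_family(family)
    k = {"JC": 0, "K80": 1, "HKY": 4, "GTR": 8}[base]
    return k + int(gamma) + int(inv)


def default_model(family: str, aln: Optional[Alignment] = None) -> SubstitutionModel:
    """A sensible starting model for optimization: empirical frequencies
    where the family frees them, kappa = 2, alpha = 0.5, p_inv = 0.1."""
    base, gamma, inv = parse_family(family)
    shape = 0.5 if gamma else None
    p_inv = 0.1 if inv else 0.0
    freqs = (
        tuple(aln.base_frequencies())
        if aln is not None and base in ("HKY", "GTR")
        else (0.25, 0.25, 0.25, 0.25)
    )
    if base == "JC":
        m = jc(shape, p_inv)
    elif base == "K80":
        m = k80(2.0, shape, p_inv)
    elif base == "HKY":
        m = hky(2.0, freqs, shape, p_inv)
    else:
        m = gtr((1, 2, 1, 1, 2, 1), freqs, shape, p_inv)
    return m.with_(name=family_name(base, gamma, inv))


def _pack(model: SubstitutionModel, family: str) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    base, gamma, inv = parse_family(family)
    theta: List[float] = []
    bounds: List[Tuple[float, float]] = []
    LOG_LO, LOG_HI = math.log(1e-3), math.log(2e2)
    ex = model.exchangeabilities
    if base in ("K80", "HKY"):
        theta.append(math.log(max(ex[1], 1e-3)))
        bounds.append((LOG_LO, LOG_HI))
    elif base == "GTR":
        for s in ex[:5]:
            theta.append(math.log(max(s, 1e-3)))
            bounds.append((LOG_LO, LOG_HI))
    if base in ("HKY", "GTR"):
        pi = model.pi
        for i in range(3):  # weights relative to pi_T
            theta.append(math.log(max(pi[i] / pi[3], 1e-3)))
            bounds.append((LOG_LO, LOG_HI))
    if gamma:
        theta.append(math.log(model.gamma_shape or 0.5))
        bounds.append((math.log(0.02), math.log(1e4)))
    if inv:
        theta.append(model.p_inv)
        bounds.append((0.0, 0.9))
    return np.asarray(theta), bounds


def _unpack(theta: np.ndarray, family: str, template: SubstitutionModel) -> SubstitutionModel:
    base, gamma, inv = parse_family(family)
    i = 0
    ex = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs = (0.25, 0.25, 0.25, 0.25)
    if base in ("K80", "HKY"):
        kappa = math.exp(theta[i]); i += 1
        ex = (1.0, kappa, 1.0, 1.0, kappa, 1.0)
    elif base == "GTR":
        vals = [math.exp(v) for v in theta[i:i + 5]]; i += 5
        ex = tuple(vals) + (1.0,)
    if base in ("HKY", "GTR"):
        w = np.exp(theta[i:i + 3]); i += 3
        total = w.sum() + 1.0
        freqs = (w[0] / total, w[1] / total, w[2] / total, 1.0 / total)
    shape = None
    if gamma:
        shape = math.exp(theta[i]); i += 1
    p_inv = 0.0
    if inv:
        p_inv = float(theta[i]); i += 1
    return SubstitutionModel(
        ex, freqs, shape, p_inv, template.n_rate_categories,
        name=family_name(base, gamma, inv),
    )


# ---------------------------------------------------------------------------
# Starting tree: neighbor joining on JC distances
# ---------------------------------------------------------------------------

def jc_distance_matrix(aln: Alignment, taxa: Optional[Sequence[str]] = None) -> np.ndarray:
    """Pairwise Jukes-Cantor distances (saturation capped at p = 0.70)."""
    taxa = list(taxa) if taxa is not None else list(aln.taxa)
    n = len(taxa)
    codes = np.vstack([aln.row(t) for t in taxa])
    plain = np.isin(codes, (1, 2, 4, 8))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = plain[i] & plain[j]
            tot = int(ok.sum())
            p = float(np.mean(codes[i][ok] != codes[j][ok])) if tot else 0.0
            p = min(p, 0.70)
            D[i, j] = D[j, i] = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return D


def starting_tree(aln: Alignment, taxa: Optional[Sequence[str]] = None) -> PhyloTree:
    """Greedy distance start tree: neighbor joining on JC distances."""
    from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor
    from Bio import Phylo

    taxa = list(taxa) if taxa is not None else list(aln.taxa)
    D = jc_distance_matrix(aln, taxa)
    matrix = [[float(D[i, j]) for j in range(i + 1)] for i in range(len(taxa))]
    dm = DistanceMatrix(names=list(taxa), matrix=matrix)
    nj = DistanceTreeConstructor().nj(dm)
    buf = _io.StringIO()
    Phylo.write(nj, buf, "newick")
    tree = parse_newick(buf.getvalue())
    for node in tree.postorder():
        if not node.is_leaf:
            node.name = None  # drop "InnerN" labels
        if node.parent is not None:
            node.length = max(node.length if node.length is not None else 0.1, 1e-4)
    return tree.unroot() if tree.rooted else tree


# ---------------------------------------------------------------------------
# Branch-length optimization
# ---------------------------------------------------------------------------

def _unrooted_edge_ids(tree: PhyloTree) -> List[FrozenSet[str]]:
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    seen: List[FrozenSet[str]] = []
    got = set()
    for node in tree.postorder():
        if node.parent is None:
            continue
        side = frozenset(l.name for l in node.leaves())
        canon = side if ref not in side else all_leaves - side
        if canon not in got:
            got.add(canon)
            seen.append(canon)
    return seen


def _locate_edge_child(tree: PhyloTree, side: FrozenSet[str]) -> Node:
    comp = tree.leaf_names() - side
    best = None
    for node in tree.postorder():
        if node.parent is None:
            continue
        below = frozenset(l.name for l in node.leaves())
        if below == side:
            return node
        if below == comp:
            best = node
    if best is None:
        raise TreeError(f"edge not present: {sorted(side)}")
    return best


def _optimize_one_edge(
    engine: PruningEngine,
    tree: PhyloTree,
    model: SubstitutionModel,
    v: Node,
    xatol: float,
) -> float:
    _reroot_at_node(tree, v.parent)
    f = engine.make_edge_objective(tree, model, v)
    res = minimize_scalar(
        lambda t: -f(t),
        bounds=(MIN_BRANCH, MAX_BRANCH),
        method="bounded",
        options={"xatol": xatol},
    )
    x, fx = float(res.x), float(-res.fun)
    if xatol < 1e-8 and MIN_BRANCH < x < MAX_BRANCH:
        # bounded Brent bottoms out near sqrt(eps)*|x|; Newton-polish on a
        # finite-difference derivative recovers the last decade of accuracy
        for h in (1e-5, 1e-6):
            g1 = (f(x + h) - f(x - h)) / (2 * h)
            g2 = (f(x + h) - 2 * fx + f(x - h)) / (h * h)
            if g2 < 0 and abs(g1 / g2) < 1e-4:
                cand = x - g1 / g2
                fc = f(cand)
                if fc >= fx:
                    x, fx = cand, fc
    if fx >= f(v.length):
        v.length = x
        return fx
    return f(v.length)


def optimize_branch_lengths(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 50,
    engine: Optional[PruningEngine] = None,
    xatol: float = 1e-7,
) -> Tuple[PhyloTree, float]:
    """Coordinate-wise branch-length optimization.

    Sweeps every edge with bracketed Brent search on the edge-profile
    likelihood until the total lnL improves by less than ``tol`` per sweep
    (or ``max_sweeps``).  Missing lengths start at 0.1.  The returned lnL is
    non-decreasing across sweeps.
    """
    work = tree.copy()
    work.set_default_lengths(0.1)
    if engine is None:
        engine = PruningEngine(aln, taxa=sorted(work.leaf_names()))
    lnl = engine.log_likelihood(work, model)
    if not np.isfinite(lnl):
        raise TreeError(
            "non-finite log-likelihood at start: check that the alignment, "
            "tree and model refer to the same taxa and valid states"
        )
    for _ in range(max_sweeps):
        for side in _unrooted_edge_ids(work):
            v = _locate_edge_child(work, side)
            new_lnl = _optimize_one_edge(engine, work, model, v, xatol)
        if new_lnl < lnl + tol:
            lnl = max(lnl, new_lnl)
            break
        lnl = new_lnl
    return work, float(lnl)


# ---------------------------------------------------------------------------
# Model-parameter optimization
# ---------------------------------------------------------------------------

def optimize_model_parameters(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    family: Optional[str] = None,
    rounds: int = 2,
    tol: float = 1e-6,
    max_iter: int = 60,
    engine: Optional[PruningEngine] = None,
    optimize_branches: bool = True,
) -> Tuple[PhyloTree, SubstitutionModel, float]:
    """Fit substitution-model parameters, interleaved with branch sweeps.

    Exchangeabilities and frequency weights are optimized in log space and
    ``p_inv`` on its natural bounded scale with L-BFGS-B; each round ends
    with a branch-length sweep.  lnL is non-decreasing across rounds; on
    optimizer non-convergence the best parameters seen are returned.
    """
    if family is None:
        family = model.name if model.name in DEFAULT_CANDIDATES else "GTR+G+I"
    base, gamma, inv = parse_family(family)
    model = model.with_(
        gamma_shape=(model.gamma_shape or 0.5) if gamma else None,
        p_inv=model.p_inv if inv else 0.0,
        name=family_name(base, gamma, inv),
    )
    work = tree.copy()
    work.set_default_lengths(0.1)
    if engine is None:
        engine = PruningEngine(aln, taxa=sorted(work.leaf_names()))
    if optimize_branches:
        # branches first: model fits at wildly wrong lengths mislead L-BFGS-B
        work, lnl = optimize_branch_lengths(
            work, aln, model, tol=tol, max_sweeps=8, engine=engine
        )
    else:
        lnl = engine.log_likelihood(work, model)
    n_params = n_free_model_parameters(family)
    edges = work.edges()
    for _ in range(max(rounds, 1)):
        if n_params:
            # joint bounded search over model parameters AND log branch
            # lengths: the strong p_inv/alpha/tree-length correlations make
            # pure alternation converge too slowly
            theta_m, bounds_m = _pack(model, family)
            n_m = len(theta_m)
            if optimize_branches:
                theta0 = np.concatenate(
                    [theta_m, [math.log(max(e.length, 1e-7)) for e in edges]]
                )
                bounds = bounds_m + [
                    (math.log(MIN_BRANCH), math.log(MAX_BRANCH))
                ] * len(edges)
            else:
                theta0, bounds = theta_m, bounds_m
            best = {"lnl": -np.inf, "theta": theta0}

            def neg(theta: np.ndarray) -> float:
                try:
                    m = _unpack(theta[:n_m], family, model)
                except Exception:
                    return 1e12
                if optimize_branches:
                    for e, lt in zip(edges, theta[n_m:]):
                        e.length = math.exp(lt)
                val = engine.log_likelihood(work, m)
                if np.isfinite(val) and val > best["lnl"]:
                    best["lnl"], best["theta"] = val, theta.copy()
                return -val if np.isfinite(val) else 1e12

            minimize(
                neg, theta0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": max_iter, "ftol": 1e-11},
            )
            neg(best["theta"])  # restore the best state seen
            model = _unpack(best["theta"][:n_m], family, model)
            lnl = best["lnl"]
        if optimize_branches:
            work, lnl = optimize_branch_lengths(
                work, aln, model, tol=tol, max_sweeps=5, engine=engine
            )
            edges = work.edges()
    return work, model, float(lnl)


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------

@dataclass
class MLResult:
    """Outcome of a maximum-likelihood search."""

    tree: PhyloTree
    model: SubstitutionModel
    lnL: float
    n_free_parameters: int
    trace: List[Tuple[str, float]] = field(default_factory=list)

    def report(self) -> str:
        lines = [
            "Maximum-likelihood inference",
            f"  lnL = {self.lnL:.6f}",
            f"  free parameters = {self.n_free_parameters}",
            f"  model: {self.model.describe()}",
            "  search trace:",
        ]
        for move, lnl in self.trace:
            lines.append(f"    {move}: lnL = {lnl:.6f}")
        return "\n".join(lines)


def _nni_with_affected(
    tree: PhyloTree, edge: Tuple[str, ...]
) -> List[Tuple[PhyloTree, List[Node]]]:
    """NNI neighbors plus the nodes whose edges the swap perturbs."""
    work = tree.unroot() if tree.rooted else tree.copy()
    child = _find_edge_node(work, tuple(edge))
    _reroot_at_node(work, child.parent)
    u = work.root
    want = frozenset(edge)
    comp = work.leaf_names() - want
    v = None
    for ch in u.children:
        if ch.is_leaf:
            continue
        side = frozenset(l.name for l in ch.leaves())
        if side in (want, comp):
            v = ch
            break
    if v is None:
        raise TreeError(f"not an internal edge: {edge}")
    others = [c for c in u.children if c is not v]
    a = others[0]
    out = []
    for c in list(v.children):
        t2 = work.copy()
        u2 = t2.root
        v2 = u2.children[u.children.index(v)]
        a2 = u2.children[u.children.index(a)]
        c2 = v2.children[v.children.index(c)]
        u2.children[u2.children.index(a2)] = c2
        v2.children[v2.children.index(c2)] = a2
        a2.parent, c2.parent = v2, u2
        affected = [v2] + list(v2.children) + [x for x in u2.children if x is not v2]
        out.append((PhyloTree(t2.root), affected))
    return out


def ml_search(
    aln: Alignment,
    model: Union[SubstitutionModel, str],
    start: Union[PhyloTree, str] = "auto",
    seed: int = 0,
    optimize_model: bool = True,
    tol: float = 1e-6,
    max_iterations: int = 50,
    model_rounds: int = 2,
) -> MLResult:
    """Heuristic ML topology search by best-improvement NNI hill climbing.

    The start tree is either supplied or built by neighbor joining on JC
    distances.  Each iteration scores every NNI neighbor of every internal
    edge (re-optimizing the five branch lengths around the swap), accepts the
    best improving move and re-sweeps all branches; the search stops when no
    neighbor improves the likelihood, then model parameters and branch
    lengths get a final full optimization.  lnL never decreases along the
    returned trace.
    """
    if isinstance(model, str):
        family: Optional[str] = model
        model = default_model(family, aln)
    else:
        family = model.name if optimize_model else None
    taxa = sorted(aln.taxa)
    if len(taxa) < 4:
        raise TreeError(f"ML search needs at least 4 taxa, got {len(taxa)}")
    engine = PruningEngine(aln, taxa=taxa)
    if isinstance(start, str):
        tree = starting_tree(aln)
    else:
        tree = start.copy()
        tree = tree.unroot() if tree.rooted else tree
    tree.set_default_lengths(0.1)
    trace: List[Tuple[str, float]] = []
    if optimize_model and family is not None:
        tree, model, lnl = optimize_model_parameters(
            tree, aln, model, family=family, rounds=1, engine=engine
        )
    else:
        tree, lnl = optimize_branch_lengths(tree, aln, model, engine=engine)
    trace.append(("start", lnl))

    for _ in range(max_iterations):
        best_lnl = lnl
        best_tree: Optional[PhyloTree] = None
        best_desc = ""
        for edge in internal_edges(tree):
            for alt, affected in _nni_with_affected(tree, edge):
                for node in affected:
                    if node.parent is not None:
                        _optimize_one_edge(engine, alt, model, node, 1e-5)
                        # _optimize_one_edge reroots; re-fetch validity
                cand = engine.log_likelihood(alt, model)
                if cand > best_lnl + tol:
                    best_lnl, best_tree = cand, alt
                    best_desc = f"nni across {{{','.join(edge)}}}"
        if best_tree is None:
            break
        tree, lnl = optimize_branch_lengths(best_tree, aln, model, engine=engine)
        lnl = max(lnl, best_lnl)
        trace.append((best_desc, lnl))

    if optimize_model and family is not None:
        tree, model, lnl2 = optimize_model_parameters(
            tree, aln, model, family=family, rounds=model_rounds, engine=engine
        )
        lnl = max(lnl, lnl2)
    else:
        tree, lnl2 = optimize_branch_lengths(tree, aln, model, engine=engine)
        lnl = max(lnl, lnl2)
    trace.append(("final", lnl))
    n_free = (2 * len(taxa) - 3) + (
        n_free_model_parameters(model.name) if model.name in DEFAULT_CANDIDATES else 0
    )
    return MLResult(tree=tree, model=model, lnL=float(lnl), n_free_parameters=n_free, trace=trace)


# ---------------------------------------------------------------------------
# AIC model selection
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionResult:
    """Per-candidate fits and the AIC-minimal choice (ties -> fewer params)."""

    rows: List[Dict[str, object]]
    selected: str

    def selected_row(self) -> Dict[str, object]:
        return next(r for r in self.rows if r["name"] == self.selected)

    def report(self) -> str:
        lines = ["Model selection (AIC = 2K - 2 lnL)"]
        for r in sorted(self.rows, key=lambda r: r["aic"]):
            mark = " *" if r["name"] == self.selected else ""
            lines.append(
                f"  {r['name']:<8} K={r['K']:>3} lnL={r['lnL']:>14.4f} AIC={r['aic']:>14.4f}{mark}"
            )
        return "\n".join(lines)


def aic_select(
    aln: Alignment,
    tree: PhyloTree,
    candidates: Optional[Sequence[str]] = None,
    rounds: int = 2,
) -> ModelSelectionResult:
    """Fit each candidate family on the fixed topology and pick minimal AIC.

    Branch lengths are re-optimized per candidate; K counts branch lengths
    plus the model parameters actually free in that family.  Ties break
    toward fewer parameters, then name, so the result does not depend on
    candidate order.
    """
    cands = list(candidates) if candidates is not None else list(DEFAULT_CANDIDATES)
    if not cands:
        raise ValueError("empty candidate list")
    engine = PruningEngine(aln, taxa=sorted(tree.leaf_names()))
    n_branches = 2 * tree.n_leaves - 3
    rows: List[Dict[str, object]] = []
    for name in cands:
        fam = family_name(*parse_family(name))
        try:
            fitted_tree, fitted_model, lnl = optimize_model_parameters(
                tree, aln, default_model(fam, aln), family=fam,
                rounds=rounds, engine=engine,
            )
        except Exception as exc:
            raise RuntimeError(f"fitting candidate {fam} failed: {exc}") from exc
        K = n_branches + n_free_model_parameters(fam)
        rows.append(
            {
                "name": fam, "lnL": float(lnl), "K": K,
                "aic": 2.0 * K - 2.0 * float(lnl),
                "model": fitted_model, "tree": fitted_tree,
            }
        )
    selected = min(rows, key=lambda r: (r["aic"], r["K"], r["name"]))["name"]
    return ModelSelectionResult(rows=rows, selected=selected)


# ---------------------------------------------------------------------------
# Nonparametric bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: Alignment,
    model: SubstitutionModel,
    ml_tree: PhyloTree,
    n_reps: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
) -> Dict[FrozenSet[str], float]:
    """Split support by nonparametric bootstrap.

    Each replicate resamples alignment columns with replacement and reruns
    the NNI search started from the ML tree (model parameters held at their
    ML estimates); the support of each split in ``ml_tree`` is the fraction
    of replicate trees containing it.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    target = bipartition_set(ml_tree)
    hits = {split: 0 for split in target}
    for _ in range(n_reps):
        rep = aln.resample_columns(rng.integers(aln.length, size=aln.length))
        # each replicate is analysed like the original data, from its own
        # distance start tree: hill-climbing started at the ML tree would
        # freeze on likelihood plateaus and inflate weak supports to 1
        res = ml_search(rep, model, optimize_model=False, tol=tol)
        found = bipartition_set(res.tree)
        for split in target:
            if split in found:
                hits[split] += 1
    return {split: hits[split] / n_reps for split in target}
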