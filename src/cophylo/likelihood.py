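"""Phylogenetic likelihood by Felsenstein's pruning algorithm.

The per-site likelihood under the +G+I mixture is

    L(site) = p_inv * pi_x * [site constant for state x]
            + (1 - p_inv) * (1/k) * sum_c L_site(rate_c)

with ``L_site(r)`` computed by post-order pruning (conditional likelihoods per
state propagated tipward-to-rootward through ``P = exp(Q t r)``) and a root
summation over the stationary distribution.  For a reversible model the value
does not depend on where the traversal is rooted.

Alignment columns are compressed to unique site patterns; results are mapped
back so callers always see per-original-column values (as the SH test's RELL
resampling requires).  Underflow is controlled by per-node rescaling of the
conditional likelihoods with the scaling factors accumulated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignment import Alignment
from .model import SubstitutionModel, build_rate_matrix, rate_matrix_eigen
from .tree import PhyloTree, TreeError

__all__ = ["SiteLikelihoods", "PruningEngine", "tree_log_likelihood"]

_TINY = 1e-300


@dataclass
class SiteLikelihoods:
    """Per-column log-likelihoods; ``total`` is their sum."""

    values: np.ndarray

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def __len__(self) -> int:
        return len(self.values)


class PruningEngine:
    """Reusable likelihood evaluator for one alignment (pattern-compressed).

    Build once per alignment (optionally restricted to the taxa of interest),
    then call :meth:`log_likelihood` repeatedly with different trees and
    models — the optimizers and the MCMC sampler do exactly that.
    """

    def __init__(self, aln: Alignment, taxa: Optional[Sequence[str]] = None):
        self.taxa: List[str] = list(taxa) if taxa is not None else list(aln.taxa)
        missing = [t for t in self.taxa if t not in aln.sequences]
        if missing:
            raise TreeError(f"leaves without sequences: {missing}")
        rows = np.vstack([aln.row(t) for t in self.taxa]) if self.taxa else np.zeros((0, 0), np.uint8)
        self.n_sites = rows.shape[1]
        if self.n_sites:
            patterns, self.pattern_index, counts = np.unique(
                rows, axis=1, return_inverse=True, return_counts=True
            )
        else:
            patterns = np.zeros((len(self.taxa), 0), np.uint8)
            self.pattern_index = np.zeros(0, dtype=np.intp)
            counts = np.zeros(0)
        self.pattern_counts = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        # tip partial vectors: taxon -> (4, n_patterns) 0/1 mask
        bits = np.array([1, 2, 4, 8], dtype=np.uint8)
        self._tip: Dict[str, np.ndarray] = {}
        for i, t in enumerate(self.taxa):
            self._tip[t] = ((patterns[i][None, :] & bits[:, None]) > 0).astype(float)
        # per-pattern constant-site mask: state x compatible with every tip
        if self.taxa:
            const = np.ones((4, self.n_patterns))
            for t in self.taxa:
                const *= self._tip[t]
        else:
            const = np.ones((4, self.n_patterns))
        self._const_mask = const

    # ------------------------------------------------------------------
    def _pattern_log_likelihoods(
        self, tree: PhyloTree, model: SubstitutionModel
    ) -> np.ndarray:
        leaves = tree.leaf_names()
        extra = leaves - set(self.taxa)
        if extra:
            raise TreeError(f"tree leaves missing from alignment: {sorted(extra)}")
        pi = model.pi
        Q = build_rate_matrix(model)
        w, U, U_inv = rate_matrix_eigen(Q, pi)
        rates = model.category_rates()
        k = len(rates)
        npat = self.n_patterns

        nodes = list(tree.postorder())
        # transition matrices for every edge x category in one shot
        lengths = []
        for node in nodes:
            if node.parent is None:
                continue
            if node.length is None:
                label = node.name if node.is_leaf else f"above {{{','.join(sorted(l.name for l in node.leaves()))}}}"
                raise TreeError(f"missing branch length on edge {label}")
            lengths.append(node.length)
        tr = np.multiply.outer(np.asarray(lengths), rates)  # (E, k)
        expw = np.exp(tr[..., None] * w[None, None, :])  # (E, k, 4)
        P = (U[None, None, :, :] * expw[:, :, None, :]) @ U_inv  # (E, k, 4, 4)
        np.clip(P, 0.0, None, out=P)

        partial: Dict[int, np.ndarray] = {}
        logscale: Dict[int, np.ndarray] = {}
        e = 0
        edge_of: Dict[int, int] = {}
        for node in nodes:
            if node.parent is not None:
                edge_of[id(node)] = e
                e += 1
        for node in nodes:
            if node.is_leaf:
                continue
            acc: Optional[np.ndarray] = None
            ls: Optional[np.ndarray] = None
            for ch in node.children:
                Pe = P[edge_of[id(ch)]]  # (k, 4, 4)
                if ch.is_leaf:
                    contrib = Pe @ self._tip[ch.name]  # (k,4,4)@(4,npat)
                else:
                    contrib = Pe @ partial.pop(id(ch))
                    ls = logscale.pop(id(ch)) if ls is None else ls + logscale.pop(id(ch))
                acc = contrib if acc is None else acc * contrib
            if ls is None:
                ls = np.zeros((k, npat))
            smax = acc.max(axis=1)  # (k, npat)
            smax_safe = np.where(smax > 0, smax, 1.0)
            acc = acc / smax_safe[:, None, :]
            ls = ls + np.log(np.where(smax > 0, smax_safe, _TINY))
            partial[id(node)] = acc
            logscale[id(node)] = ls

        root = nodes[-1]
        rootL = (pi[None, :, None] * partial[id(root)]).sum(axis=1)  # (k, npat)
        x = np.log(np.maximum(rootL, _TINY)) + logscale[id(root)]
        xmax = x.max(axis=0)
        log_var = xmax + np.log(np.exp(x - xmax[None, :]).mean(axis=0))

        p_inv = model.p_inv
        if p_inv > 0:
            const_pi = pi @ self._const_mask  # (npat,)
            with np.errstate(divide="ignore"):
                log_const = np.log(p_inv * const_pi)
            out = np.logaddexp(log_const, np.log1p(-p_inv) + log_var)
        else:
            out = log_var
        return out

    def make_edge_objective(self, tree: PhyloTree, model: SubstitutionModel, v):
        """Total lnL as a cheap function of one branch length.

        ``v`` must be a child of ``tree.root``.  The conditional likelihoods
        of ``v``'s subtree and of the rest of the tree are computed once; the
        returned callable re-evaluates only ``exp(Q t r)`` across the focal
        edge, which makes per-edge Brent optimization an order of magnitude
        cheaper than full re-evaluation.
        """
        if v.parent is not tree.root:
            raise TreeError("make_edge_objective expects a child of the root")
        pi = model.pi
        Q = build_rate_matrix(model)
        w, U, U_inv = rate_matrix_eigen(Q, pi)
        rates = model.category_rates()
        k = len(rates)
        npat = self.n_patterns

        nodes = list(tree.postorder())
        lengths = []
        for node in nodes:
            if node.parent is None:
                continue
            if node.length is None:
                raise TreeError("missing branch length")
            lengths.append(node.length)
        tr = np.multiply.outer(np.asarray(lengths), rates)
        expw = np.exp(tr[..., None] * w[None, None, :])
        P = (U[None, None, :, :] * expw[:, :, None, :]) @ U_inv
        np.clip(P, 0.0, None, out=P)
        edge_of: Dict[int, int] = {}
        e = 0
        for node in nodes:
            if node.parent is not None:
                edge_of[id(node)] = e
                e += 1

        partial: Dict[int, np.ndarray] = {}
        logscale: Dict[int, np.ndarray] = {}
        root = tree.root
        for node in nodes:
            if node.is_leaf or node is root:
                continue
            acc: Optional[np.ndarray] = None
            ls: Optional[np.ndarray] = None
            for ch in node.children:
                Pe = P[edge_of[id(ch)]]
                if ch.is_leaf:
                    contrib = Pe @ self._tip[ch.name]
                else:
                    contrib = Pe @ partial.pop(id(ch))
                    ls = logscale.pop(id(ch)) if ls is None else ls + logscale.pop(id(ch))
                acc = contrib if acc is None else acc * contrib
            if ls is None:
                ls = np.zeros((k, npat))
            smax = acc.max(axis=1)
            smax_safe = np.where(smax > 0, smax, 1.0)
            partial[id(node)] = acc / smax_safe[:, None, :]
            logscale[id(node)] = ls + np.log(np.where(smax > 0, smax_safe, _TINY))

        # rest-of-tree profile at the root, excluding v's subtree
        A = np.broadcast_to(pi[None, :, None], (k, 4, npat)).copy()
        ls_A = np.zeros((k, npat))
        for ch in root.children:
            if ch is v:
                continue
            Pe = P[edge_of[id(ch)]]
            if ch.is_leaf:
                A = A * (Pe @ self._tip[ch.name])
            else:
                A = A * (Pe @ partial[id(ch)])
                ls_A = ls_A + logscale[id(ch)]
        if v.is_leaf:
            F_down = np.broadcast_to(self._tip[v.name][None, :, :], (k, 4, npat))
            ls_down = np.zeros((k, npat))
        else:
            F_down = partial[id(v)]
            ls_down = logscale[id(v)]
        ls_total = ls_A + ls_down
        p_inv = model.p_inv
        if p_inv > 0:
            const_pi = pi @ self._const_mask
            with np.errstate(divide="ignore"):
                log_const = np.log(p_inv * const_pi)
        counts = self.pattern_counts

        def objective(t: float) -> float:
            expv = np.exp(np.multiply.outer(t * rates, w))  # (k, 4)
            Pv = (U[None, :, :] * expv[:, None, :]) @ U_inv
            np.clip(Pv, 0.0, None, out=Pv)
            val = (A * (Pv @ F_down)).sum(axis=1)  # (k, npat)
            x = np.log(np.maximum(val, _TINY)) + ls_total
            xmax = x.max(axis=0)
            log_var = xmax + np.log(np.exp(x - xmax[None, :]).mean(axis=0))
            if p_inv > 0:
                per_pat = np.logaddexp(log_const, np.log1p(-p_inv) + log_var)
            else:
                per_pat = log_var
            return float(per_pat @ counts)

        return objective

    def site_log_likelihoods(
        self, tree: PhyloTree, model: SubstitutionModel
    ) -> SiteLikelihoods:
        """Per-original-column log-likelihoods."""
        per_pattern = self._pattern_log_likelihoods(tree, model)
        return SiteLikelihoods(per_pattern[self.pattern_index])

    def log_likelihood(self, tree: PhyloTree, model: SubstitutionModel) -> float:
        """Total log-likelihood (pattern counts, no per-site expansion)."""
        per_pattern = self._pattern_log_likelihoods(tree, model)
        return float(per_pattern @ self.pattern_counts)


def tree_log_likelihood(
    tree: PhyloTree, aln: Alignment, model: SubstitutionModel
) -> SiteLikelihoods:
    """Log-likelihood of ``aln`` on ``tree`` under ``model``, per column.

    Gaps, ``N`` and IUPAC ambiguity codes are treated as partial/missing
    observations.  Branch lengths must be present on every edge.
    """
    engine = PruningEngine(aln, taxa=sorted(tree.leaf_names()))
    return engine.site_log_likelihoods(tree, model)
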