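"""Posterior tree samples: the ordered output of a Bayesian MCMC run."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .tree import PhyloTree

__all__ = ["PosteriorSample"]


@dataclass
class PosteriorSample:
    """An ordered collection of sampled trees with burn-in metadata.

    ``trees`` are in sampling order.  ``parameters`` optionally carries the
    scalar trace (lnL, alpha, p_inv, ...) aligned with ``trees``.
    ``burnin_applied`` records whether the leading fraction has already been
    discarded; :meth:`without_burnin` is idempotent once it has.
    """

    trees: List[PhyloTree]
    parameters: Optional[Dict[str, List[float]]] = None
    burnin_applied: bool = False
    provenance: Dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def without_burnin(self, fraction: float = 0.25) -> "PosteriorSample":
        if self.burnin_applied:
            return self
        if not 0 <= fraction < 1:
            raise ValueError(f"burn-in fraction must be in [0,1), got {fraction}")
        start = math.floor(len(self.trees) * fraction)
        params = None
        if self.parameters is not None:
            params = {k: v[start:] for k, v in self.parameters.items()}
        return PosteriorSample(
            trees=self.trees[start:],
            parameters=params,
            burnin_applied=True,
            provenance=dict(self.provenance, burnin_fraction=fraction),
        )
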