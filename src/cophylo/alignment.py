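"""Nucleotide alignment container.

Sequences are stored both as strings (for faithful round-tripping) and as a
matrix of 4-bit state masks (bit 0 = A, 1 = C, 2 = G, 3 = T) so that IUPAC
ambiguity codes become partial observations: ``R`` is ``A|G``, ``N``/``-``/
``?`` match everything.  ``U`` is normalised to ``T`` on input.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = ["Alignment", "CODE_OF", "AlignmentError"]


class AlignmentError(ValueError):
    pass


CODE_OF: Dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7,
    "N": 15, "-": 15, "?": 15, ".": 15,
}

_CODE_TABLE = np.zeros(256, dtype=np.uint8)
for _ch, _code in CODE_OF.items():
    _CODE_TABLE[ord(_ch)] = _code
    _CODE_TABLE[ord(_ch.lower())] = _code

_CHAR_OF_CODE = {v: k for k, v in CODE_OF.items() if k not in ("U", "?", ".")}
_CHAR_OF_CODE[15] = "N"


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_TABLE[raw]
    if np.any(codes == 0):
        bad = seq[int(np.argmax(codes == 0))]
        raise AlignmentError(f"invalid nucleotide character {bad!r}")
    return codes


class Alignment:
    """Equal-length nucleotide sequences keyed by unique taxon names."""

    def __init__(self, records: Iterable[Tuple[str, str]]):
        pairs = list(records)
        if not pairs:
            raise AlignmentError("empty alignment")
        self.taxa: List[str] = [name for name, _ in pairs]
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxa: {dupes}")
        lengths = {len(seq) for _, seq in pairs}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences: Dict[str, str] = {n: s.upper().replace("U", "T") for n, s in pairs}
        self.codes = np.vstack([_encode(s) for _, s in pairs])

    # -- accessors -------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def __len__(self) -> int:
        return self.length

    def sequence(self, taxon: str) -> str:
        return self.sequences[taxon]

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxa.index(taxon)]

    # -- column resampling (bootstrap / RELL) ----------------------------
    def resample_columns(self, indices: Sequence[int]) -> "Alignment":
        idx = np.asarray(indices, dtype=np.intp)
        records = []
        for i, name in enumerate(self.taxa):
            seq = self.sequences[name]
            records.append((name, "".join(seq[j] for j in idx)))
        return Alignment(records)

    def bootstrap(self, rng: np.random.Generator) -> "Alignment":
        """Resample columns with replacement (same length, same taxa)."""
        return self.resample_columns(rng.integers(self.length, size=self.length))

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        return Alignment([(t, self.sequences[t]) for t in taxa])

    def base_frequencies(self) -> np.ndarray:
        """Empirical A,C,G,T frequencies over unambiguous sites."""
        counts = np.zeros(4)
        for b, bit in enumerate((1, 2, 4, 8)):
            counts[b] = int(np.sum(self.codes == bit))
        total = counts.sum()
        if total == 0:
            return np.full(4, 0.25)
        return counts / total

    def __repr__(self) -> str:
        return f"<Alignment n_taxa={self.n_taxa} length={self.length}>"
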