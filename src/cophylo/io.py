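"""File formats: FASTA alignments, NEXUS tree samples, association tables.

FASTA goes through Biopython.  The NEXUS support targets the MrBayes ``.t``
dialect — a ``trees`` block with a ``Translate`` table and numbered tree
statements — but also tolerates files without a Translate block whose tips
are written as (possibly quoted) names.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import Alignment
from .posterior import PosteriorSample
from .tree import HostAssociation, PhyloTree, parse_newick, write_newick

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_nexus_trees",
    "write_nexus_trees",
    "read_association",
    "write_association",
]

PathOrStr = Union[str, Path]


class NexusError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: PathOrStr) -> Alignment:
    """Read an aligned FASTA file (or raw FASTA text) into an Alignment."""
    text: str
    p = Path(source)
    if str(source).lstrip().startswith(">"):
        text = str(source)
    else:
        text = p.read_text()
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(_io.StringIO(text), "fasta")]
    return Alignment(records)


def write_fasta(aln: Alignment, path: PathOrStr, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(t)), id=t, description="") for t in aln.taxa
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# NEXUS trees block (MrBayes .t dialect)
# ---------------------------------------------------------------------------

_TREE_STMT = re.compile(
    r"^\s*tree\s+(\S+)\s*=\s*(.*)$", re.IGNORECASE
)


def _strip_nexus_comments(text: str) -> str:
    # remove [...] comments except those inside quoted labels
    out: List[str] = []
    depth = 0
    in_quote = False
    i = 0
    while i < len(text):
        c = text[i]
        if in_quote:
            out.append(c)
            if c == "'":
                if i + 1 < len(text) and text[i + 1] == "'":
                    out.append("'")
                    i += 1
                else:
                    in_quote = False
        elif depth > 0:
            if c == "]":
                depth -= 1
            elif c == "[":
                depth += 1
        elif c == "[":
            depth += 1
        else:
            out.append(c)
            if c == "'":
                in_quote = True
        i += 1
    return "".join(out)


def _parse_translate(block: str) -> Dict[str, str]:
    table: Dict[str, str] = {}
    body = block.strip().rstrip(";")
    for entry in body.split(","):
        entry = entry.strip()
        if not entry:
            continue
        parts = entry.split(None, 1)
        if len(parts) != 2:
            raise NexusError(f"malformed Translate entry: {entry!r}")
        num, name = parts
        name = name.strip()
        if name.startswith("'") and name.endswith("'"):
            name = name[1:-1].replace("''", "'")
        table[num] = name
    return table


def read_nexus_trees(source: PathOrStr) -> PosteriorSample:
    """Read a NEXUS trees block into a :class:`PosteriorSample`.

    Trees come back in file order with tip numbers replaced through the
    Translate table; burn-in is *not* applied.  A tip number missing from the
    Translate table is an error naming that number.
    """
    text = str(source)
    if "begin trees" not in text.lower():
        text = Path(source).read_text()
    clean = _strip_nexus_comments(text)
    m = re.search(r"begin\s+trees\s*;(.*?)end\s*;", clean, re.IGNORECASE | re.DOTALL)
    if not m:
        raise NexusError("no trees block found")
    block = m.group(1)
    translate: Optional[Dict[str, str]] = None
    tm = re.search(r"translate\b(.*?);", block, re.IGNORECASE | re.DOTALL)
    if tm:
        translate = _parse_translate(tm.group(1))
        block = block[: tm.start()] + block[tm.end():]
    trees: List[PhyloTree] = []
    for stmt in block.split(";"):
        stmt = stmt.strip()
        sm = _TREE_STMT.match(stmt)
        if not sm:
            continue
        tree = parse_newick(sm.group(2) + ";")
        if translate is not None:
            for leaf in tree.leaves():
                if leaf.name not in translate:
                    raise NexusError(
                        f"tip number {leaf.name!r} missing from Translate table"
                    )
                leaf.name = translate[leaf.name]
        trees.append(PhyloTree(tree.root))
    if not trees:
        raise NexusError("trees block contains no tree statements")
    return PosteriorSample(trees=trees, burnin_applied=False)


def write_nexus_trees(
    sample: PosteriorSample,
    path: PathOrStr,
    tree_name_prefix: str = "gen",
) -> None:
    """Write trees as a NEXUS trees block with a Translate table."""
    taxa = sorted(sample.trees[0].leaf_names())
    number_of = {name: i + 1 for i, name in enumerate(taxa)}
    lines = ["#NEXUS", "begin trees;", "   translate"]
    for i, name in enumerate(taxa):
        sep = "," if i < len(taxa) - 1 else ";"
        safe = f"'{name}'" if re.search(r"[\s(),:;\[\]']", name) else name
        lines.append(f"      {i + 1} {safe}{sep}")
    for k, tree in enumerate(sample.trees):
        t = tree.copy()
        for leaf in t.leaves():
            leaf.name = str(number_of[leaf.name])
        lines.append(f"   tree {tree_name_prefix}_{k} = [&U] {write_newick(t)}")
    lines.append("end;")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Virus -> host association TSV
# ---------------------------------------------------------------------------

def read_association(source: PathOrStr) -> HostAssociation:
    """Read a two-column tab-delimited virus→host table ('#' comments allowed)."""
    s = str(source)
    if isinstance(source, Path) or ("\n" not in s and "\t" not in s):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = s
    mapping: Dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"association line {lineno}: expected 2 tab-separated fields, got {len(parts)}"
            )
        virus, host = parts[0].strip(), parts[1].strip()
        if virus in mapping:
            raise ValueError(f"association line {lineno}: duplicate virus taxon {virus!r}")
        mapping[virus] = host
    return HostAssociation(mapping)


def write_association(assoc: HostAssociation, path: PathOrStr) -> None:
    lines = ["#virus_taxon\thost_taxon"]
    for virus, host in sorted(assoc.items()):
        lines.append(f"{virus}\t{host}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
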