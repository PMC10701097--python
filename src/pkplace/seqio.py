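"""Sequence, tree and placement I/O, plus the integer k-mer codec.

Alignments are plain named lists of gapped strings over a declared alphabet
(DNA or amino acid).  K-mers are packed into integers by positional base-σ
expansion, which is the key used throughout the phylo-k-mer database.
Placements are written in the jplace (version 3) JSON format on an
edge-numbered Newick string.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO as _BioSeqIO

DNA = "DNA"
AA = "AA"

# rank order A=0, C=1, G=2, T=3 for DNA; alphabetical for amino acids
ALPHABETS = {
    DNA: "ACGT",
    AA: "ACDEFGHIKLMNPQRSTVWY",
}
GAP_CHARS = frozenset("-.")

_RANK = {alpha: {c: i for i, c in enumerate(chars)} for alpha, chars in ALPHABETS.items()}

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class UnencodableKmer(ValueError):
    """Raised when a word contains a gap or ambiguity code and cannot be packed."""


def sigma(alphabet: str) -> int:
    """Alphabet size: 4 for DNA, 20 for amino acids."""
    return len(ALPHABETS[alphabet])


@dataclass
class Alignment:
    """A reference multiple sequence alignment.

    Rows are upper-case gapped strings of identical length over ``alphabet``;
    names are unique identifiers in the same order as rows.
    """

    names: list[str]
    rows: list[str]
    alphabet: str = DNA

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows must have the same length")
        if not self.rows:
            raise ValueError("alignment has no sequences")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names in alignment")
        L = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            if len(row) != L:
                raise ValueError(
                    f"unequal lengths: sequence {name!r} has length {len(row)}, expected {L}"
                )
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def degapped(self, name: str) -> str:
        """Sequence with gap characters removed."""
        seq = self.row(name)
        return "".join(c for c in seq if c not in GAP_CHARS)


def read_alignment(path: str | Path, alphabet: str = DNA) -> Alignment:
    """Read a FASTA alignment; sequences are upper-cased and length-checked."""
    names: list[str] = []
    rows: list[str] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not names:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment(names=names, rows=rows, alphabet=alphabet)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n{row}\n")


def read_queries(path: str | Path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Read query reads from FASTA or FASTQ as (name, sequence) pairs.

    FASTQ quality strings are discarded; only the sequence is used.  The
    format is inferred from the extension unless given explicitly.
    """
    p = Path(path)
    if fmt is None:
        fmt = "fastq" if p.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in _BioSeqIO.parse(str(p), fmt)]


# ---------------------------------------------------------------------------
# k-mer codec
# ---------------------------------------------------------------------------


def encode_kmer(word: str, alphabet: str = DNA) -> int:
    """Pack ``word`` into an integer in [0, σ^k) by positional base-σ expansion.

    The leftmost character is the most significant digit.  Raises
    :class:`UnencodableKmer` on gaps or ambiguity codes; callers skip such
    windows.
    """
    rank = _RANK[alphabet]
    s = len(rank)
    code = 0
    for c in word:
        r = rank.get(c)
        if r is None:
            raise UnencodableKmer(f"unencodable character {c!r} in k-mer {word!r}")
        code = code * s + r
    return code


def decode_kmer(code: int, k: int, alphabet: str = DNA) -> str:
    chars = ALPHABETS[alphabet]
    s = len(chars)
    out = []
    for _ in range(k):
        code, r = divmod(code, s)
        out.append(chars[r])
    return "".join(reversed(out))


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (non-ACGT characters pass through)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def read_tree(path: str | Path, auto_root: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    The root must be a bifurcation.  With ``auto_root`` an unrooted
    (basal-multifurcating) tree is rooted at the midpoint of its longest
    leaf-to-leaf path; otherwise such input is an error, since the ghost
    branch length convention depends on correct rooting.  Every branch must
    carry a length.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return _validate_tree(tree, auto_root=auto_root)


def tree_from_string(newick: str, auto_root: bool = False) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return _validate_tree(tree, auto_root=auto_root)


def _validate_tree(tree: dendropy.Tree, auto_root: bool) -> dendropy.Tree:
    root = tree.seed_node
    n_children = len(root.child_nodes())
    if n_children != 2:
        if not auto_root:
            raise ValueError(
                "tree must be rooted (root bifurcation expected, found "
                f"{n_children} children); pass auto_root to midpoint-root"
            )
        tree.reroot_at_midpoint(update_bipartitions=False)
        root = tree.seed_node
        if len(root.child_nodes()) != 2:
            raise ValueError("midpoint rooting failed to produce a bifurcating root")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else "(internal)"
            raise ValueError(f"missing branch length on edge above {label!r}")
    return tree


def check_tree_matches_alignment(tree: dendropy.Tree, aln: Alignment) -> None:
    """Leaves and alignment rows must be in one-to-one correspondence."""
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    aln_names = set(aln.names)
    missing = sorted(leaf_labels - aln_names)
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {missing}")
    extra = sorted(aln_names - leaf_labels)
    if extra:
        raise ValueError(f"alignment sequences absent from tree: {extra}")


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# jplace
# ---------------------------------------------------------------------------

JPLACE_FIELDS = [
    "edge_num",
    "likelihood",
    "like_weight_ratio",
    "distal_length",
    "pendant_length",
]


def write_jplace(
    results: Iterable,
    edge_numbered_newick: str,
    path: str | Path,
    invocation: str = "pkplace",
) -> None:
    """Write placements as a jplace version-3 document.

    ``results`` is an iterable of :class:`pkplace.placement.PlacementResult`.
    Each reported row is ``[edge_num, likelihood, like_weight_ratio,
    distal_length, pendant_length]``.  Unplaced queries appear with an empty
    row list.  Edge numbers are validated against the ``{n}`` annotations of
    the tree string.
    """
    known_edges = _edge_numbers_in_newick(edge_numbered_newick)
    placements = []
    for res in results:
        rows = []
        for row in res.jplace_rows():
            if row[0] not in known_edges:
                raise ValueError(
                    f"placement of {res.name!r} references unknown edge {row[0]}"
                )
            rows.append(list(row))
        placements.append({"p": rows, "n": [res.name]})
    doc = {
        "version": 3,
        "tree": edge_numbered_newick,
        "fields": JPLACE_FIELDS,
        "placements": placements,
        "metadata": {"invocation": invocation},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_jplace(path: str | Path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != 3:
        raise ValueError("expected jplace version 3")
    return doc


def _edge_numbers_in_newick(newick: str) -> set[int]:
    import re

    return {int(m) for m in re.findall(r"\{(\d+)\}", newick)}
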