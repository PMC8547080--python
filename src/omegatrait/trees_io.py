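"""Trees, codon alignments and phenotype tables.

The working objects of the pipeline are a rooted species tree with branch
lengths and foreground/background branch labels, in-frame codon alignments,
and a species-to-testicular-position phenotype table.  This module owns
parsing/writing of those formats (newick, FASTA, TSV) and the Brownian-motion
covariance matrix used by the phylogenetic regressions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BACKGROUND = 0
FOREGROUND = 1

# codon-matrix state codes for non-standard columns
GAP = -1      # alignment gap ("---")
MISSING = -2  # ambiguous or partially gapped codon; likelihood sees all-ones

_STOP_CODONS = {"TAA", "TAG", "TGA"}

#: the 61 sense codons of the standard genetic code, alphabetical order
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}


class TreeParseError(ValueError):
    """Malformed newick or invalid tree structure."""


class AlignmentError(ValueError):
    """Invalid codon alignment (frame, length or stop-codon violations)."""


class PhyloTree:
    """Rooted phylogeny stored as flat arrays for fast traversal.

    Nodes are indexed ``0 .. n_nodes-1``; ``parent[root] == -1``.  Branch
    ``i`` is the edge above node ``i`` (undefined for the root).  Branch
    classes partition non-root branches into foreground (1) and
    background (0) lineages for the branch and branch-site codon models.
    """

    def __init__(
        self,
        parent: np.ndarray,
        length: np.ndarray,
        names: list[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.names = list(names)
        self.n_nodes = len(self.names)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeParseError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.tip_indices = [i for i in range(self.n_nodes) if not self.children[i]]
        self.tip_labels = [self.names[i] for i in self.tip_indices]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dup = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise TreeParseError(f"duplicate tip labels: {', '.join(dup)}")
        if not np.all(np.isfinite(self.length[[i for i in range(self.n_nodes) if i != self.root]])):
            raise TreeParseError("non-finite branch length")
        if np.any(self.length[[i for i in range(self.n_nodes) if i != self.root]] < 0):
            raise TreeParseError("negative branch length")
        # postorder: children before parents
        self.postorder: list[int] = []
        stack = [self.root]
        order = []
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.preorder = order
        self.postorder = order[::-1]
        self.branch_class = np.full(self.n_nodes, BACKGROUND, dtype=np.int8)
        self.branch_class[self.root] = -1

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)

    def copy(self) -> "PhyloTree":
        t = PhyloTree(self.parent.copy(), self.length.copy(), list(self.names))
        t.branch_class = self.branch_class.copy()
        return t

    # ------------------------------------------------------------- queries
    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_indices[self.tip_labels.index(label)]
        except ValueError:
            raise KeyError(f"tip {label!r} not in tree") from None

    def root_to_tip_nodes(self, label: str) -> list[int]:
        """Nodes on the path root -> tip, excluding the root (= the branches)."""
        path = []
        v = self.tip_index(label)
        while v != self.root:
            path.append(v)
            v = int(self.parent[v])
        return path[::-1]

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            if v != self.root:
                d[v] = d[self.parent[v]] + self.length[v]
        return d

    def descendant_tips(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def branch_indices(self) -> list[int]:
        """All non-root node indices (each owns the branch above it)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def total_length(self) -> float:
        return float(sum(self.length[i] for i in self.branch_indices()))


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted newick string with branch lengths.

    Raises :class:`TreeParseError` on malformed input or duplicate tips,
    naming the offending token.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed newick: {exc}") from exc
    nodes = list(dt.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    length = np.zeros(len(nodes))
    names: list[str | None] = [None] * len(nodes)
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise TreeParseError(
                    f"missing branch length above node {nd.taxon.label if nd.taxon else i!r}"
                )
            length[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeParseError("unlabeled tip")
            names[i] = nd.taxon.label
        elif nd.taxon is not None:
            names[i] = nd.taxon.label
    return PhyloTree(parent, length, names)


def write_newick(tree: PhyloTree) -> str:
    """Serialize with shortest-exact float representations, so branch
    lengths round-trip bit-exactly through the parser."""

    def render(v: int) -> str:
        if not tree.children[v]:
            s = tree.names[v] or ""
        else:
            s = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        if v != tree.root:
            s += f":{float(tree.length[v])!r}"
        return s

    return render(tree.root) + ";"


def brownian_covariance(tree: PhyloTree, labels: list[str] | None = None) -> pd.DataFrame:
    """Shared root-to-tip path length matrix (Brownian-motion covariance).

    ``C[i, j]`` is the summed length of branches common to the root-to-i and
    root-to-j paths, i.e. the depth of the most recent common ancestor of the
    two tips.  Symmetric and positive semi-definite by construction.
    """
    labels = labels if labels is not None else tree.tip_labels
    tip_pos = {tree.tip_index(l): k for k, l in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    for v in tree.branch_indices():
        below = [tip_pos[t] for t in tree.descendant_tips(v) if t in tip_pos]
        if below:
            idx = np.array(below)
            C[np.ix_(idx, idx)] += tree.length[v]
    return pd.DataFrame(C, index=labels, columns=labels)


def label_branches(
    tree: PhyloTree,
    foreground_tips: set[str] | frozenset[str] | list[str],
    mode: str = "tips_and_pure_clades",
) -> PhyloTree:
    """Return a copy with branch classes set from a foreground species set.

    ``tips_only`` marks only the terminal branches of foreground species;
    ``tips_and_pure_clades`` (default) additionally marks every internal
    branch whose descendant tips are all foreground, so that wholly
    ascrotal clades (e.g. cetaceans) contribute their stem and internal
    branches.  Idempotent.
    """
    fg = set(foreground_tips)
    unknown = sorted(fg - set(tree.tip_labels))
    if unknown:
        raise KeyError(f"unknown foreground species: {', '.join(unknown)}")
    if mode not in ("tips_only", "tips_and_pure_clades"):
        raise ValueError(f"unknown labeling mode {mode!r}")
    out = tree.copy()
    out.branch_class[:] = BACKGROUND
    out.branch_class[out.root] = -1
    fg_tip_idx = {out.tip_index(l) for l in fg}
    for v in out.branch_indices():
        if not out.children[v]:
            if v in fg_tip_idx:
                out.branch_class[v] = FOREGROUND
        elif mode == "tips_and_pure_clades":
            if all(t in fg_tip_idx for t in out.descendant_tips(v)):
                out.branch_class[v] = FOREGROUND
    return out


def restrict_to_taxa(tree: PhyloTree, labels) -> PhyloTree:
    """Subtree induced by a taxon subset; unifurcations are collapsed by
    summing branch lengths.  Branch classes are not carried over (relabel
    after restriction)."""
    keep = set(labels)
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")

    def sub(v: int) -> tuple[str, float] | None:
        if not tree.children[v]:
            name = tree.names[v]
            return (name, float(tree.length[v])) if name in keep else None
        parts = [r for c in tree.children[v] if (r := sub(c)) is not None]
        if not parts:
            return None
        if len(parts) == 1:
            s, l = parts[0]
            return (s, l + float(tree.length[v]))
        s = "(" + ",".join(f"{p}:{pl:.12g}" for p, pl in parts) + ")"
        return (s, float(tree.length[v]))

    parts = [r for c in tree.children[tree.root] if (r := sub(c)) is not None]
    if not parts:
        raise ValueError("no taxa retained")
    if len(parts) == 1:
        s, l = parts[0]
        text = (f"({s}:{l:.12g});" if "(" not in s else s + ";")
    else:
        text = "(" + ",".join(f"{p}:{pl:.12g}" for p, pl in parts) + ");"
    return PhyloTree.from_newick(text)


# --------------------------------------------------------------- phenotypes

TWO_CLASS_CODES = {"scrotal": 0, "ascrotal": 1}
THREE_CLASS_CODES = {"CDT": 0, "IDT": 1, "UDT": 2}


@dataclass
class PhenotypeMap:
    """Species -> testicular-position labels.

    Two-class: scrotal / ascrotal.  Three-class: CDT (completely descended,
    scrotal), IDT (incompletely descended, inguinal), UDT (undescended,
    abdominal).  Consistency (scrotal <=> CDT, ascrotal <=> IDT|UDT) is
    enforced at construction.
    """

    class2: dict[str, str] = field(default_factory=dict)
    class3: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.class2) != set(self.class3):
            raise ValueError("two-class and three-class tables cover different species")
        for sp in self.class2:
            c2, c3 = self.class2[sp], self.class3[sp]
            if c2 not in TWO_CLASS_CODES:
                raise ValueError(f"{sp}: invalid two-class label {c2!r}")
            if c3 not in THREE_CLASS_CODES:
                raise ValueError(f"{sp}: invalid three-class label {c3!r}")
            if (c2 == "scrotal") != (c3 == "CDT"):
                raise ValueError(f"{sp}: inconsistent labels ({c2}, {c3})")

    @property
    def species(self) -> list[str]:
        return sorted(self.class2)

    def foreground_species(self, group: str = "ascrotal") -> set[str]:
        """Species in a named phenotype group (ascrotal, scrotal, CDT, IDT, UDT)."""
        if group in TWO_CLASS_CODES:
            return {s for s, c in self.class2.items() if c == group}
        if group in THREE_CLASS_CODES:
            return {s for s, c in self.class3.items() if c == group}
        raise KeyError(f"unknown phenotype group {group!r}")

    def encode(self, scheme: str = "two_class") -> pd.Series:
        """Numeric encoding: scrotal=0/ascrotal=1, or CDT=0/IDT=1/UDT=2."""
        if scheme == "two_class":
            return pd.Series({s: TWO_CLASS_CODES[c] for s, c in self.class2.items()}, dtype=float)
        if scheme == "three_class":
            return pd.Series({s: THREE_CLASS_CODES[c] for s, c in self.class3.items()}, dtype=float)
        raise ValueError(f"unknown encoding scheme {scheme!r}")

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"species", "class2", "class3"}
        if not required.issubset(df.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        return cls(
            class2=dict(zip(df["species"], df["class2"])),
            class3=dict(zip(df["species"], df["class3"])),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "species": self.species,
                "class2": [self.class2[s] for s in self.species],
                "class3": [self.class3[s] for s in self.species],
            }
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------- codon alignment


class CodonAlignment:
    """In-frame multi-species codon alignment over the 61 sense codons.

    Stored as an integer matrix (taxa x codon columns): ``0..60`` index into
    :data:`SENSE_CODONS`; ``GAP`` marks ``---`` columns and ``MISSING`` marks
    codons containing ambiguity characters or partial gaps, which contribute
    all-ones partial likelihoods.  Internal stop codons are rejected.
    """

    def __init__(self, taxa: list[str], codon_matrix: np.ndarray) -> None:
        self.taxa = list(taxa)
        self.codons = np.asarray(codon_matrix, dtype=np.int16)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise AlignmentError("codon matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def __len__(self) -> int:
        return len(self.taxa)

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "CodonAlignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise AlignmentError("sequences have unequal lengths")
        (L,) = lengths
        if L % 3:
            raise AlignmentError(f"alignment length {L} not divisible by 3")
        mat = np.empty((len(taxa), L // 3), dtype=np.int16)
        for r, (name, seq) in enumerate(seqs.items()):
            s = seq.upper().replace("U", "T")
            for c in range(L // 3):
                codon = s[3 * c : 3 * c + 3]
                if codon == "---":
                    mat[r, c] = GAP
                elif codon in _STOP_CODONS:
                    raise AlignmentError(
                        f"stop codon {codon} in taxon {name!r} at codon column {c + 1}"
                    )
                elif codon in CODON_INDEX:
                    mat[r, c] = CODON_INDEX[codon]
                else:
                    mat[r, c] = MISSING
        return cls(taxa, mat)

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        return cls.from_sequences({r.id: str(r.seq) for r in records})

    def to_fasta(self, path) -> None:
        records = []
        for r, name in enumerate(self.taxa):
            seq = "".join(
                "---" if s == GAP else ("NNN" if s == MISSING else SENSE_CODONS[s])
                for s in self.codons[r]
            )
            records.append(SeqRecord(Seq(seq), id=name, description=""))
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta-2line")

    def to_string(self) -> str:
        buf = io.StringIO()
        for r, name in enumerate(self.taxa):
            seq = "".join(
                "---" if s == GAP else ("NNN" if s == MISSING else SENSE_CODONS[s])
                for s in self.codons[r]
            )
            buf.write(f">{name}\n{seq}\n")
        return buf.getvalue()

    def subset_taxa(self, taxa: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(taxa, self.codons[idx])
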