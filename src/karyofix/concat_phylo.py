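"""Concatenated-SNP sequences, ambiguity-aware distances, and NJ trees.

Because DArT alleles are unphased, each individual's genotype at a locus
becomes one IUPAC character: call 0 the ref base, call 2 the alt base,
call 1 the two-base ambiguity code, missing 'N'.  Concatenating the
characters over all loci of a scaffold (ordered by position) gives one
sequence per individual — positionally homologous by construction, so no
multiple alignment is needed.  Distances are expected allelic
p-distances, trees are Saitou–Nei neighbor joining with midpoint rooting,
and FASTA/NEXUS exports let users rerun external likelihood software.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix
from .locus_mapping import LocusAssignment

#: IUPAC code for each unordered base pair.
AMBIGUITY = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
#: Base set carried by each alignment character.
CHAR_BASES = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    **{code: pair for pair, code in AMBIGUITY.items()},
}


@dataclass(frozen=True)
class ConcatAlignment:
    individuals: tuple[str, ...]
    sequences: tuple[str, ...]
    locus_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.individuals) != len(self.sequences):
            raise ValueError("one sequence per individual required")
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise ValueError("sequences must be equal length")
        if self.sequences and lens != {len(self.locus_order)}:
            raise ValueError("sequence length must equal number of loci")
        allowed = set(CHAR_BASES) | {"N"}
        for ind, seq in zip(self.individuals, self.sequences):
            bad = set(seq) - allowed
            if bad:
                raise ValueError(f"{ind}: characters outside IUPAC set: {sorted(bad)}")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        self.values = v


@dataclass
class TreeNode:
    """Tree node with child edges carrying branch lengths."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return [leaf for child, _ in self.children for leaf in child.leaves()]

    def to_newick(self) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label or ""
            parts = [f"{rec(c)}:{bl:.10g}" for c, bl in node.children]
            return "(" + ",".join(parts) + ")"

        return rec(self) + ";"

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path-length metric implied by the tree."""

        def leafdists(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}  # type: ignore[dict-item]
            out: dict[str, float] = {}
            for child, bl in node.children:
                for leaf, dd in leafdists(child).items():
                    out[leaf] = dd + bl
            return out

        paths: dict[tuple[str, str], float] = {}

        def visit(node: TreeNode) -> None:
            if node.is_leaf:
                return
            sub = [
                {leaf: dd + bl for leaf, dd in leafdists(child).items()}
                for child, bl in node.children
            ]
            for a_i in range(len(sub)):
                for b_i in range(a_i + 1, len(sub)):
                    for la, da in sub[a_i].items():
                        for lb, db in sub[b_i].items():
                            key = (la, lb) if la < lb else (lb, la)
                            paths[key] = da + db
            for child, _ in node.children:
                visit(child)

        visit(self)
        return paths


def parse_newick(text: str) -> TreeNode:
    """Minimal newick reader (labels and branch lengths, no support values)."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                child, bl = parse_node()
                node.children.append((child, bl))
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ",();":
            pos += 1
        token = text[start:pos]
        label, _, bl_text = token.partition(":")
        if label:
            node.label = label
        return node, float(bl_text) if bl_text else 0.0

    root, _ = parse_node()
    return root


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concat_sequences(
    matrix: GenotypeMatrix,
    assignments: Sequence[LocusAssignment],
    scaffold: str,
) -> ConcatAlignment:
    """One IUPAC character per locus of ``scaffold`` per individual.

    Loci are ordered by scaffold start ascending (ties by locus id).  When
    a locus lacks ref/alt metadata the alphabetically first of {A, G}
    stands for ref/alt deterministically — call patterns, not base
    identities, carry the phylogenetic signal here.
    """
    on_scaf = [a for a in assignments if a.scaffold == scaffold]
    if not on_scaf:
        raise KeyError(f"no assignments on scaffold {scaffold!r}")
    on_scaf.sort(key=lambda a: (a.start, a.locus_id))
    row_of = {loc.id: i for i, loc in enumerate(matrix.loci)}
    loci_meta = {loc.id: loc for loc in matrix.loci}

    columns: list[str] = []
    order: list[str] = []
    for a in on_scaf:
        if a.locus_id not in row_of:
            raise KeyError(f"assignment references unknown locus {a.locus_id!r}")
        loc = loci_meta[a.locus_id]
        ref = loc.ref_allele or "A"
        alt = loc.alt_allele or ("G" if ref != "G" else "A")
        if ref == alt:
            raise ValueError(f"locus {loc.id!r}: ref == alt")
        het = AMBIGUITY[frozenset((ref, alt))]
        charmap = {0: ref, 1: het, 2: alt, MISSING: "N"}
        columns.append("".join(charmap[int(c)] for c in matrix.calls[row_of[a.locus_id]]))
        order.append(a.locus_id)

    seqs = ["".join(col[j] for col in columns) for j in range(matrix.n_individuals)]
    return ConcatAlignment(tuple(matrix.individual_ids()), tuple(seqs), tuple(order))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _site_weight(c1: str, c2: str) -> float:
    # identical genotypes (incl. het vs same het) are 0; disjoint base sets 1;
    # genotypes sharing one allele (homo vs het containing it) 0.5.
    if c1 == c2:
        return 0.0
    s1, s2 = CHAR_BASES[c1], CHAR_BASES[c2]
    return 1.0 if s1.isdisjoint(s2) else 0.5


def p_distance(alignment: ConcatAlignment) -> DistanceMatrix:
    """Expected allelic p-distance between every pair of sequences.

    Sites where either character is N are excluded per pair; the distance
    is the mean site weight over included sites.  A pair with no included
    sites raises.
    """
    if len(alignment.sequences) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(alignment.sequences)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = alignment.sequences[i], alignment.sequences[j]
            total = 0.0
            count = 0
            for a, b in zip(si, sj):
                if a == "N" or b == "N":
                    continue
                total += _site_weight(a, b)
                count += 1
            if count == 0:
                raise ValueError(
                    f"{alignment.individuals[i]} and {alignment.individuals[j]} "
                    "share no non-missing sites"
                )
            out[i, j] = out[j, i] = total / count
    return DistanceMatrix(list(alignment.individuals), out)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj(dist: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining (unrooted).

    The Q criterion is minimized with ties broken by the lexicographically
    smallest (sorted) pair of cluster representative labels.  A negative
    branch length is clamped to zero and the deficit moved to its sister
    branch, preserving the pair's summed length.
    """
    labels = list(dist.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    if n == 2:
        root = TreeNode()
        root.children = [
            (TreeNode(labels[0]), float(dist.values[0, 1])),
            (TreeNode(labels[1]), 0.0),
        ]
        return root

    D = {frozenset((a, b)): float(dist.values[i, j])
         for i, a in enumerate(labels) for j, b in enumerate(labels) if i < j}
    nodes: dict[str, TreeNode] = {lab: TreeNode(lab) for lab in labels}
    active = list(labels)
    counter = itertools.count()

    def d(a: str, b: str) -> float:
        return D[frozenset((a, b))]

    while len(active) > 3:
        r = len(active)
        sums = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (r - 2) * d(a, b) - sums[a] - sums[b]
            key = (q, tuple(sorted((a, b))))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best  # type: ignore[misc]
        bl_a = 0.5 * d(a, b) + (sums[a] - sums[b]) / (2 * (r - 2))
        bl_b = d(a, b) - bl_a
        if bl_a < 0:
            bl_b += bl_a
            bl_a = 0.0
        if bl_b < 0:
            bl_a += bl_b
            bl_b = 0.0
        bl_a, bl_b = max(bl_a, 0.0), max(bl_b, 0.0)
        new_label = f"__internal_{next(counter)}"
        parent = TreeNode()
        parent.children = [(nodes[a], bl_a), (nodes[b], bl_b)]
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            D[frozenset((new_label, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = [c for c in active if c not in (a, b)] + [new_label]

    a, b, c = sorted(active)
    bl_a = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    bl_b = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    bl_c = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = TreeNode()
    root.children = [
        (nodes[a], max(bl_a, 0.0)),
        (nodes[b], max(bl_b, 0.0)),
        (nodes[c], max(bl_c, 0.0)),
    ]
    return root


def _adjacency(tree: TreeNode) -> tuple[dict[int, list[tuple[int, float]]],
                                        dict[int, str], dict[str, int]]:
    """Undirected edge list over node ids, plus leaf label maps."""
    adj: dict[int, list[tuple[int, float]]] = {}
    leaf_label: dict[int, str] = {}
    leaf_id: dict[str, int] = {}

    def walk(node: TreeNode) -> None:
        adj.setdefault(id(node), [])
        if node.is_leaf:
            leaf_label[id(node)] = node.label  # type: ignore[assignment]
            leaf_id[node.label] = id(node)  # type: ignore[index]
        for child, bl in node.children:
            adj.setdefault(id(child), [])
            adj[id(node)].append((id(child), bl))
            adj[id(child)].append((id(node), bl))
            walk(child)

    walk(tree)
    return adj, leaf_label, leaf_id


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the smallest (sorted)
    leaf-label pair.  With all path lengths zero the root lands on the
    first edge along the tie-broken path.  The input tree is not modified.
    """
    paths = tree.path_lengths()
    if not paths:
        return tree
    (la, lb), longest = min(paths.items(), key=lambda kv: (-kv[1], kv[0]))
    target = longest / 2.0

    adj, leaf_label, leaf_id = _adjacency(tree)

    # node-id chain from la to lb: nodes[i] -- edges[i] -- nodes[i+1]
    def find_path(src: int, dst: int) -> tuple[list[int], list[float]]:
        stack = [(src, -1)]
        prev: dict[int, tuple[int, float]] = {}
        while stack:
            cur, parent = stack.pop()
            if cur == dst:
                break
            for nb, bl in adj[cur]:
                if nb != parent and nb not in prev:
                    prev[nb] = (cur, bl)
                    stack.append((nb, cur))
        nodes = [dst]
        edges: list[float] = []
        while nodes[-1] != src:
            p, bl = prev[nodes[-1]]
            nodes.append(p)
            edges.append(bl)
        nodes.reverse()
        edges.reverse()
        return nodes, edges

    nodes_chain, edges_chain = find_path(leaf_id[la], leaf_id[lb])

    # find the edge containing the midpoint, measured from la
    acc = 0.0
    lo = hi = nodes_chain[0]
    into = 0.0
    edge_len = 0.0
    for k, bl in enumerate(edges_chain):
        if acc + bl >= target - 1e-12 or k == len(edges_chain) - 1:
            lo, hi = nodes_chain[k], nodes_chain[k + 1]
            edge_len = bl
            into = min(max(target - acc, 0.0), bl)
            break
        acc += bl

    # rebuild a rooted tree from a virtual root on edge (lo, hi)
    def build(node_id: int, parent_id: int) -> TreeNode:
        label = leaf_label.get(node_id)
        children = [
            (build(nb, node_id), bl) for nb, bl in adj[node_id] if nb != parent_id
        ]
        out = TreeNode(label)
        out.children = children
        # suppress a degree-2 pass-through node created by removing the edge
        return out

    root = TreeNode()
    side_lo = build(lo, hi)
    side_hi = build(hi, lo)
    root.children = [(side_lo, into), (side_hi, edge_len - into)]
    return _suppress_unifurcations(root)


def _suppress_unifurcations(node: TreeNode) -> TreeNode:
    """Collapse unlabeled degree-1 internal nodes by summing branch lengths."""
    new_children: list[tuple[TreeNode, float]] = []
    for child, bl in node.children:
        child = _suppress_unifurcations(child)
        if not child.is_leaf and len(child.children) == 1 and child.label is None:
            grand, gbl = child.children[0]
            new_children.append((grand, bl + gbl))
        else:
            new_children.append((child, bl))
    out = TreeNode(node.label)
    out.children = new_children
    return out


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_alignment(alignment: ConcatAlignment, fmt: str = "fasta") -> str:
    """Serialize as FASTA or NEXUS (data block, ambiguity symbols declared)."""
    if not alignment.sequences:
        raise ValueError("empty alignment")
    if fmt == "fasta":
        return "".join(
            f">{ind}\n{seq}\n" for ind, seq in zip(alignment.individuals, alignment.sequences)
        )
    if fmt == "nexus":
        ntax = len(alignment.individuals)
        nchar = len(alignment.sequences[0])
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={ntax} NCHAR={nchar};",
            "  FORMAT DATATYPE=DNA MISSING=N GAP=- SYMBOLS=\"ACGT\";",
            "  MATRIX",
        ]
        width = max(len(ind) for ind in alignment.individuals) + 2
        for ind, seq in zip(alignment.individuals, alignment.sequences):
            lines.append(f"    {ind:<{width}}{seq}")
        lines += ["  ;", "END;", ""]
        return "\n".join(lines)
    raise ValueError(f"unknown format {fmt!r}")


def read_nexus_alignment(text: str) -> dict[str, str]:
    """Read back the sequences of a NEXUS data block (round-trip helper)."""
    seqs: dict[str, str] = {}
    in_matrix = False
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if stripped == ";" or stripped.upper().startswith("END"):
                break
            if stripped:
                name, seq = stripped.split(None, 1)
                seqs[name] = seqs.get(name, "") + seq.replace(" ", "")
    return seqs
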