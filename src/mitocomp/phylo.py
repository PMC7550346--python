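"""Distance-based phylogenetics: neighbor joining, midpoint rooting,
monophyly tests, Newick I/O, and supermatrix export for external
Bayesian/ML inference.

Neighbor joining is the classical Saitou-Nei algorithm with the Q
criterion and deterministic lowest-index tie-breaking, so identical
inputs give bit-identical trees.  Bayesian inference and maximum
likelihood are deliberately not reimplemented: the module writes NEXUS
(with an MrBayes block), relaxed PHYLIP and partition files for the
external tools, and topology claims are checked on the NJ tree.
"""

from __future__ import annotations

import copy
import itertools
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .divergence import DistanceMatrix
from .genome import PCG_ORDER, Mitogenome, feature_sequence

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.name for lf in self.leaves())

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every node in the subtree (preorder)."""
        out = [self.leaf_names()]
        for c in self.children:
            out.extend(c.clades())
        return out

    def newick(self, digits: int = 17) -> str:
        return self._newick_part(digits) + ";"

    def _newick_part(self, digits: int) -> str:
        if self.is_leaf:
            body = self.name or ""
        else:
            inner = ",".join(c._newick_part(digits) for c in self.children)
            body = f"({inner})" + (self.name or "")
        return f"{body}:{self.length:.{digits}g}"


class NewickError(ValueError):
    pass


_TOKEN = re.compile(r"\(|\)|,|;|:[-+0-9.eE]+|[^(),:;\s]+")


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a TreeNode (lengths default to 0)."""
    tokens = _TOKEN.findall(text.strip())
    if not tokens or tokens[-1] != ";":
        raise NewickError("Newick string must end with ';'")
    root = TreeNode()
    stack: list[TreeNode] = []
    current = root
    for tok in tokens[:-1]:
        if tok == "(":
            child = TreeNode()
            current.children.append(child)
            stack.append(current)
            current = child
        elif tok == ",":
            if not stack:
                raise NewickError("',' outside parentheses")
            current = TreeNode()
            stack[-1].children.append(current)
        elif tok == ")":
            if not stack:
                raise NewickError("unbalanced ')'")
            current = stack.pop()
        elif tok.startswith(":"):
            current.length = float(tok[1:])
        else:
            current.name = tok
    if stack:
        raise NewickError("unbalanced '(' in Newick string")
    return root


# ------------------------------------------------------------------ NJ ----

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining with lowest-index tie-breaking.

    Returns an unrooted tree represented with a trifurcating root node.
    Negative branch lengths are clamped to 0 with a warning.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d: dict[tuple[int, int], float] = {
        (i, j): float(dm.matrix[i, j])
        for i in range(n) for j in range(i + 1, n)
    }
    node_of: dict[int, TreeNode] = {
        i: TreeNode(name=lab) for i, lab in enumerate(dm.labels)}
    active = list(range(n))
    next_id = n

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    def clamp(val: float) -> float:
        if val < -1e-12:
            logger.warning("negative NJ branch length %.4g clamped to 0", val)
        return max(val, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active) for i in active}
        best = None
        best_q = math.inf
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * dist(i, j) - r[i] - r[j]
            if q < best_q - 1e-12:  # strict improvement => lowest index wins ties
                best_q, best = q, (i, j)
        i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        node_of[i].length = clamp(li)
        node_of[j].length = clamp(lj)
        parent = TreeNode(children=[node_of[i], node_of[j]])
        node_of[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            d[(min(next_id, k), max(next_id, k))] = \
                0.5 * (dist(i, k) + dist(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    center = TreeNode()
    for idx, ln in ((a, 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))),
                    (b, 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))),
                    (c, 0.5 * (dist(a, c) + dist(b, c) - dist(a, b)))):
        node_of[idx].length = clamp(ln)
        center.children.append(node_of[idx])
    return center


# ------------------------------------------------------------- rooting ----

def _index_parents(tree: TreeNode) -> dict[int, TreeNode]:
    parents: dict[int, TreeNode] = {}

    def walk(node: TreeNode) -> None:
        for c in node.children:
            parents[id(c)] = node
            walk(c)

    walk(tree)
    return parents


def pairwise_leaf_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Path lengths between every pair of leaves (keys sorted)."""
    dists: dict[tuple[str, str], float] = {}

    def post(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        child_maps = [
            {k: v + c.length for k, v in post(c).items()}
            for c in node.children
        ]
        for m1, m2 in itertools.combinations(child_maps, 2):
            for x, dx in m1.items():
                for y, dy in m2.items():
                    dists[(min(x, y), max(x, y))] = dx + dy
        merged: dict[str, float] = {}
        for cm in child_maps:
            merged.update(cm)
        return merged

    post(tree)
    return dists


def reroot_on_edge(tree: TreeNode, child: TreeNode,
                   dist_from_child: float) -> TreeNode:
    """Reroot ``tree`` inside the edge above ``child`` (mutates in place).

    ``dist_from_child`` is the distance from ``child`` to the new root,
    clamped to the edge length.  Returns the new root.
    """
    parents = _index_parents(tree)
    parent = parents.get(id(child))
    if parent is None:
        return tree
    edge_len = child.length
    x = min(max(dist_from_child, 0.0), edge_len)
    # chain from parent back to the old root
    chain = [parent]
    while id(chain[-1]) in parents:
        chain.append(parents[id(chain[-1])])
    orig_len = {id(node): node.length for node in chain}
    parent.children = [c for c in parent.children if c is not child]
    for node, upper in zip(chain, chain[1:]):
        upper.children = [c for c in upper.children if c is not node]
    for node, upper in zip(chain, chain[1:]):
        node.children.append(upper)
        upper.length = orig_len[id(node)]
    child.length = x
    parent.length = edge_len - x
    new_root = TreeNode(children=[child, parent])
    _splice_unary(new_root)
    return new_root


def _splice_unary(node: TreeNode) -> None:
    """Remove internal nodes with a single child, merging branch lengths."""
    for i, c in enumerate(list(node.children)):
        _splice_unary(c)
        if not c.is_leaf and len(c.children) == 1:
            only = c.children[0]
            only.length += c.length
            node.children[i] = only


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The input tree is not modified.  Ties on the diameter pair are broken
    by sorted leaf-name order for reproducibility.
    """
    tree = copy.deepcopy(tree)
    leaves = tree.leaves()
    if len(leaves) < 2:
        return tree
    dists = pairwise_leaf_distances(tree)
    (a, b), diameter = max(dists.items(), key=lambda kv: (kv[1], kv[0]))
    if diameter <= 0:
        logger.warning("zero-diameter tree; root placed at the current node")
        return tree
    half = diameter / 2.0
    # walk from leaf a to leaf b and find the edge holding the midpoint
    parents = _index_parents(tree)
    leaf_by_name = {lf.name: lf for lf in leaves}

    def path_to_root(leaf: TreeNode) -> list[TreeNode]:
        path = [leaf]
        while id(path[-1]) in parents:
            path.append(parents[id(path[-1])])
        return path

    pa = path_to_root(leaf_by_name[a])  # a .. root
    pb = path_to_root(leaf_by_name[b])
    in_pa = {id(n): k for k, n in enumerate(pa)}
    apex_idx_b = next(k for k, n in enumerate(pb) if id(n) in in_pa)
    apex_idx_a = in_pa[id(pb[apex_idx_b])]
    # edges walked from a: upward a->apex, then downward apex->b
    acc = 0.0
    for k in range(apex_idx_a):  # edge above pa[k], entered at child side
        length = pa[k].length
        if acc + length >= half - 1e-12:
            return reroot_on_edge(tree, pa[k], half - acc)
        acc += length
    for k in range(apex_idx_b - 1, -1, -1):  # entered at parent side
        length = pb[k].length
        if acc + length >= half - 1e-12:
            return reroot_on_edge(tree, pb[k], length - (half - acc))
        acc += length
    return tree  # numerical edge case: midpoint at the far leaf


def tree_depths(tree: TreeNode) -> dict[str, float]:
    """Root-to-leaf path lengths."""
    out: dict[str, float] = {}

    def walk(node: TreeNode, depth: float) -> None:
        if node.is_leaf:
            out[node.name] = depth
        for c in node.children:
            walk(c, depth + c.length)

    walk(tree, 0.0)
    return out


def is_monophyletic(tree: TreeNode, taxa: Iterable[str]) -> bool:
    """True iff some clade of the rooted tree equals ``taxa`` exactly."""
    target = frozenset(taxa)
    leaves = tree.leaf_names()
    unknown = target - leaves
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    return target in set(tree.clades())


# --------------------------------------------------------- supermatrix ----

@dataclass
class Supermatrix:
    """Concatenated PCG blocks per taxon with 1-based partition bounds."""

    labels: list[str]
    sequences: list[str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end), 1-based

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def aligned(self) -> bool:
        return len({len(s) for s in self.sequences}) <= 1


def concatenate_pcgs(genomes: list[Mitogenome],
                     gene_order_: tuple[str, ...] = PCG_ORDER,
                     drop_incomplete: bool = True) -> Supermatrix:
    """Concatenate the 13 PCGs (sense strand) per genome in fixed order.

    Genomes missing any gene are dropped with a warning (the blocks would
    otherwise misalign).  When per-gene lengths are equal across taxa the
    result is an identity alignment; otherwise blocks are unaligned
    export material for an external aligner and partition bounds refer to
    the first taxon's coordinates.
    """
    usable: list[Mitogenome] = []
    for g in genomes:
        missing = [gene for gene in gene_order_ if g.get_feature(gene) is None]
        if missing:
            if drop_incomplete:
                logger.warning("genome %s lacks %s; dropped from supermatrix",
                               g.id, ",".join(missing))
                continue
            raise ValueError(f"genome {g.id} lacks genes {missing}")
        usable.append(g)
    if not usable:
        raise ValueError("no genome carries the full gene set")
    blocks: dict[str, list[str]] = {g.id: [] for g in usable}
    partitions: list[tuple[str, int, int]] = []
    col = 0
    for gene in gene_order_:
        width = None
        for g in usable:
            seq = feature_sequence(g, g.get_feature(gene))
            blocks[g.id].append(seq)
            if width is None:
                width = len(seq)
        partitions.append((gene, col + 1, col + width))
        col += width
    return Supermatrix(
        labels=[g.id for g in usable],
        sequences=["".join(blocks[g.id]) for g in usable],
        partitions=partitions,
    )


def write_phylip(sm: Supermatrix, handle: TextIO) -> None:
    """Relaxed PHYLIP (name, two spaces, sequence)."""
    if not sm.aligned:
        raise ValueError("unaligned supermatrix cannot be written as PHYLIP")
    handle.write(f" {len(sm.labels)} {sm.width}\n")
    for lab, seq in zip(sm.labels, sm.sequences):
        handle.write(f"{lab}  {seq}\n")


def write_partitions(sm: Supermatrix, handle: TextIO) -> None:
    """RAxML-style partition lines: 'DNA, gene = start-end'."""
    for gene, start, end in sm.partitions:
        handle.write(f"DNA, {gene} = {start}-{end}\n")


MRBAYES_BLOCK = """begin mrbayes;
  set autoclose=yes nowarn=yes;
  lset nst=6 rates=gamma;
  mcmc nruns=2 nchains=4 ngen=5000000 samplefreq=1000;
  sumt burninfrac=0.25;
  sump burninfrac=0.25;
end;
"""


def write_nexus(sm: Supermatrix, handle: TextIO,
                mrbayes_block: bool = True) -> None:
    """NEXUS data matrix with an optional MrBayes block (GTR+G settings:
    2 runs, 4 chains, 5,000,000 generations, sampling every 1000,
    25% burn-in)."""
    if not sm.aligned:
        raise ValueError("unaligned supermatrix cannot be written as NEXUS")
    handle.write("#NEXUS\n\nbegin data;\n")
    handle.write(f"  dimensions ntax={len(sm.labels)} nchar={sm.width};\n")
    handle.write("  format datatype=dna missing=N gap=-;\n  matrix\n")
    for lab, seq in zip(sm.labels, sm.sequences):
        handle.write(f"    {lab}  {seq}\n")
    handle.write("  ;\nend;\n\n")
    handle.write("begin sets;\n")
    for gene, start, end in sm.partitions:
        handle.write(f"  charset {gene} = {start}-{end};\n")
    handle.write("end;\n")
    if mrbayes_block:
        handle.write("\n" + MRBAYES_BLOCK)
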