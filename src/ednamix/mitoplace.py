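"""Branch-assigned transversion SNPs on a rooted tree, read support/conflict
tallies per partitioned read set, and greedy best-path placement.

MSA columns are the universal coordinate system: the plurality consensus has
the same length as the alignment, and reads re-mapped to that consensus carry
column coordinates directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .util import DNA, is_transversion, revcomp


# ---------------------------------------------------------------------------
# rooted tree


class TreeNode:
    __slots__ = ("index", "label", "parent", "children", "_leafset")

    def __init__(self, index: int, label: str | None = None):
        self.index = index
        self.label = label
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self._leafset: frozenset | None = None

    def leafset(self) -> frozenset:
        if self._leafset is None:
            if not self.children:
                self._leafset = frozenset([self.label])
            else:
                self._leafset = frozenset().union(*(c.leafset() for c in self.children))
        return self._leafset


class RootedTree:
    """Rooted tree with stable, permutation-invariant branch identifiers.

    The branch above a node is identified by the sorted leaf labels of the
    clade below it, joined with '|'.
    """

    def __init__(self, root: TreeNode, nodes: list[TreeNode], outgroup: str | None = None):
        self.root = root
        self.nodes = nodes
        self.outgroup = outgroup
        labels = [n.label for n in nodes if not n.children]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        if outgroup is not None and outgroup not in labels:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf")
        self._clades = {n.leafset(): n for n in nodes if n.parent is not None}

    @classmethod
    def from_newick(cls, newick: str, outgroup: str | None = None) -> "RootedTree":
        import dendropy

        try:
            dt = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises schema-specific errors
            raise ValueError(f"failed to parse newick: {exc}") from None
        if outgroup is not None:
            og = dt.find_node_with_taxon_label(outgroup)
            if og is None:
                raise ValueError(f"outgroup {outgroup!r} not found in tree")
            already = (og.parent_node is dt.seed_node
                       and len(dt.seed_node.child_nodes()) == 2)
            if not already:
                # place a binary root on the outgroup's edge
                if og.edge.length is None:
                    og.edge.length = 1.0
                dt.reroot_at_edge(og.edge, update_bipartitions=False)
                dt.suppress_unifurcations()
        nodes: list[TreeNode] = []

        def build(dnode, parent):
            node = TreeNode(len(nodes), dnode.taxon.label if dnode.taxon else None)
            node.parent = parent
            nodes.append(node)
            for child in dnode.child_nodes():
                node.children.append(build(child, node))
            return node

        root = build(dt.seed_node, None)
        return cls(root, nodes, outgroup)

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return node.label
            return "(" + ",".join(fmt(c) for c in node.children) + ")"

        return fmt(self.root) + ";"

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.children]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def branch_id(self, node: TreeNode) -> str:
        return "|".join(sorted(node.leafset()))

    def branch_for_clade(self, leafset: frozenset) -> TreeNode | None:
        return self._clades.get(leafset)

    def node_of_branch(self, branch_id: str) -> TreeNode:
        return self._clades[frozenset(branch_id.split("|"))]

    def root_path(self, leaf_label: str) -> list[str]:
        """Branch ids from the root down to (and including) the leaf branch."""
        node = next(n for n in self.nodes if n.label == leaf_label and not n.children)
        path = []
        while node.parent is not None:
            path.append(self.branch_id(node))
            node = node.parent
        return path[::-1]


# ---------------------------------------------------------------------------
# MSA handling


@dataclass
class MsaBlock:
    names: list[str]
    sequences: list[str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("all MSA rows must have equal length")
        if len(self.names) != len(self.sequences):
            raise ValueError("names/sequences length mismatch")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def row(self, name: str) -> str:
        try:
            return self.sequences[self.names.index(name)]
        except ValueError:
            raise KeyError(f"row {name!r} absent from MSA") from None

    @classmethod
    def from_fasta(cls, path) -> "MsaBlock":
        from .util import read_fasta

        records = read_fasta(path)
        return cls([n for n, _ in records], [s for _, s in records])


@dataclass
class BiallelicSite:
    column: int  # 0-based MSA column
    alleles: tuple[str, str]
    carriers: dict[str, frozenset]  # allele -> leaf names carrying it
    is_transversion: bool
    allele_anc: str | None = None  # set during branch assignment
    allele_der: str | None = None


def extract_biallelic_sites(msa: MsaBlock, transversions_only: bool = True,
                            reference_row: str | None = None) -> list[BiallelicSite]:
    """Biallelic columns of the MSA, optionally transversions only.

    Columns with a non-ACGT base in the reference row are dropped; rows with
    non-ACGT bases at a column are excluded from that column's carriers.
    """
    if reference_row is not None:
        ref_seq = msa.row(reference_row)
    sites = []
    for col in range(msa.length):
        if reference_row is not None and ref_seq[col] not in DNA:
            continue
        carriers: dict[str, set] = {}
        for name, seq in zip(msa.names, msa.sequences):
            b = seq[col]
            if b in DNA:
                carriers.setdefault(b, set()).add(name)
        if len(carriers) != 2:
            continue
        a1, a2 = sorted(carriers)
        tv = is_transversion(a1, a2)
        if transversions_only and not tv:
            continue
        sites.append(BiallelicSite(col, (a1, a2),
                                   {a: frozenset(s) for a, s in carriers.items()}, tv))
    return sites


def consensus_from_msa(msa: MsaBlock) -> str:
    """Per-column plurality base; ACGT ties break A<C<G<T; gap/N plurality -> N."""
    if not msa.sequences:
        raise ValueError("empty MSA")
    out = []
    for col in range(msa.length):
        counts = Counter(seq[col] for seq in msa.sequences)
        acgt = [(counts.get(b, 0), b) for b in DNA]
        best_n, best_b = max(acgt, key=lambda t: (t[0], -DNA.index(t[1])))
        n_other = sum(c for b, c in counts.items() if b not in DNA)
        out.append(best_b if best_n > 0 and best_n >= n_other else "N")
    return "".join(out)


def consensus_from_pileup(alignments, reads: dict[str, str], reference_length: int,
                          min_fraction: float = 0.66, min_depth: int = 3) -> str:
    """Pileup consensus: base iff depth >= min_depth and plurality fraction
    >= min_fraction, else N.  ACGT ties break A<C<G<T before the fraction test."""
    counts = [Counter() for _ in range(reference_length)]
    for rec in alignments:
        seq = reads[rec.read_id]
        if rec.strand == "-":
            seq = revcomp(seq)
        if rec.start + len(seq) > reference_length:
            raise ValueError(f"read {rec.read_id!r} extends past the reference end")
        for i, b in enumerate(seq):
            if b in DNA:
                counts[rec.start + i][b] += 1
    out = []
    for c in counts:
        depth = sum(c.values())
        if depth < min_depth:
            out.append("N")
            continue
        best_n, best_b = max(((c.get(b, 0), b) for b in DNA),
                             key=lambda t: (t[0], -DNA.index(t[1])))
        out.append(best_b if best_n / depth >= min_fraction else "N")
    return "".join(out)


# ---------------------------------------------------------------------------
# branch assignment


@dataclass
class BranchVariantMap:
    assigned: dict[str, list[int]]  # branch id -> site indices (into the site list)
    unassigned: list[tuple[int, str]]  # (site index, reason)
    sites: list[BiallelicSite]

    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())


def assign_sites_to_branches(tree: RootedTree, sites: list[BiallelicSite]) -> BranchVariantMap:
    """Assign each site to the branch on which its derived allele arose.

    A site maps to branch b iff one allele's carrier set equals the leaf set
    of the clade below b; when both alleles form clades (a root bipartition)
    the derived allele is the one on the side not containing the outgroup.
    """
    tree_leaves = set(tree.leaf_labels())
    assigned: dict[str, list[int]] = {}
    unassigned: list[tuple[int, str]] = []
    for idx, site in enumerate(sites):
        scored = set().union(*site.carriers.values())
        extra = scored - tree_leaves
        if extra:
            raise ValueError(f"MSA rows absent from the tree: {sorted(extra)}")
        matches = []
        for allele, carrier in site.carriers.items():
            node = tree.branch_for_clade(carrier)
            if node is not None:
                matches.append((allele, node))
        if not matches:
            reason = "missing-data" if scored != tree_leaves else "homoplasic"
            unassigned.append((idx, reason))
            continue
        if len(matches) == 2 and tree.outgroup is not None:
            matches = [(a, n) for a, n in matches if tree.outgroup not in n.leafset()]
        allele, node = matches[0]
        site.allele_der = allele
        site.allele_anc = next(a for a in site.alleles if a != allele)
        assigned.setdefault(tree.branch_id(node), []).append(idx)
    return BranchVariantMap(assigned, unassigned, sites)


# ---------------------------------------------------------------------------
# read support tallies and placement


def tally_branch_support(alignments, reads: dict[str, str], bvmap: BranchVariantMap,
                         consensus_length: int,
                         transversions_only: bool = True) -> dict[str, tuple[int, int]]:
    """(support, conflict) per branch for one read set on consensus coordinates.

    At each branch-assigned site covered by >= 1 read the plurality read base
    is compared with the derived/ancestral alleles; ties and third alleles
    skip the site.  Each site contributes at most once.
    """
    pile: dict[int, Counter] = {}
    wanted: dict[int, tuple[str, int]] = {}  # column -> (branch, site idx)
    for branch, idxs in bvmap.assigned.items():
        for idx in idxs:
            site = bvmap.sites[idx]
            if transversions_only and not site.is_transversion:
                continue
            wanted[site.column] = (branch, idx)
    for rec in alignments:
        seq = reads[rec.read_id]
        if rec.strand == "-":
            seq = revcomp(seq)
        if rec.start + len(seq) > consensus_length:
            raise ValueError(f"read {rec.read_id!r} exceeds the consensus length")
        for col in range(rec.start, rec.start + len(seq)):
            if col in wanted:
                b = seq[col - rec.start]
                if b in DNA:
                    pile.setdefault(col, Counter())[b] += 1
    table: dict[str, tuple[int, int]] = {}
    for col, counts in pile.items():
        branch, idx = wanted[col]
        site = bvmap.sites[idx]
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            continue  # plurality tie
        base = top[0][0]
        s, c = table.get(branch, (0, 0))
        if base == site.allele_der:
            table[branch] = (s + 1, c)
        elif base == site.allele_anc:
            table[branch] = (s, c + 1)
    return table


@dataclass
class PlacementResult:
    path: list[str]  # branch ids from the root downward
    net_scores: list[int]
    terminal_branch: str | None
    stop_reason: str


def best_path(tree: RootedTree, table: dict[str, tuple[int, int]]) -> PlacementResult:
    """Greedy root-to-tip descent accepting branches with support >= 1 and
    support - conflict > 0; stops on ties or when no child qualifies."""
    node = tree.root
    path: list[str] = []
    nets: list[int] = []
    while True:
        if not node.children:
            return PlacementResult(path, nets, path[-1] if path else None, "reached tip")
        scored = []
        for child in node.children:
            s, c = table.get(tree.branch_id(child), (0, 0))
            if s >= 1 and s - c > 0:
                scored.append((s - c, child))
        if not scored:
            reason = "no signal" if not path else "no acceptable child"
            return PlacementResult(path, nets, path[-1] if path else None, reason)
        best_net = max(net for net, _ in scored)
        winners = [child for net, child in scored if net == best_net]
        if len(winners) > 1:
            return PlacementResult(path, nets, path[-1] if path else None, "tie")
        node = winners[0]
        path.append(tree.branch_id(node))
        nets.append(best_net)


@dataclass
class DualPathReport:
    placements: dict[str, PlacementResult]  # per read-set label
    tables: dict[str, dict[str, tuple[int, int]]]
    shared_confined: bool | None  # shared support only on the common root path?
    common_branches: list[str] = field(default_factory=list)


def dual_path_report(tree: RootedTree, bvmap: BranchVariantMap,
                     alignments_by_set: dict[str, list],
                     reads_by_set: dict[str, dict[str, str]],
                     consensus_length: int,
                     transversions_only: bool = True) -> DualPathReport:
    """Placements for the unique_a / unique_b / shared read sets, plus a check
    that shared-set support is confined to the branches common to both paths."""
    tables, placements = {}, {}
    for label, alns in alignments_by_set.items():
        tables[label] = tally_branch_support(alns, reads_by_set[label], bvmap,
                                             consensus_length, transversions_only)
        placements[label] = best_path(tree, tables[label])
    confined = None
    common: list[str] = []
    labels = list(alignments_by_set)
    if "shared" in tables and len(labels) >= 3:
        unique_labels = [l for l in labels if l != "shared"][:2]
        pa = placements[unique_labels[0]].path
        pb = placements[unique_labels[1]].path
        for ba, bb in zip(pa, pb):
            if ba == bb:
                common.append(ba)
            else:
                break
        supported = {b for b, (s, c) in tables["shared"].items() if s > 0}
        confined = supported <= set(common)
    return DualPathReport(placements, tables, confined, common)
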