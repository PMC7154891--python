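"""Rooted phylogenetic trees with branch lengths, and branch-class maps.

Trees are inputs here: topologies are taken as given (no tree search).
Nodes are integer ids; every non-root node carries the branch to its
parent.  Branch-class maps partition those branches into the classes of
the hierarchical GC models (one equilibrium-GC parameter per class).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class NewickError(ValueError):
    """Malformed Newick input; message includes the character position."""


@dataclass
class PhyloTree:
    """Rooted tree stored as parent-pointer arrays.

    parent[i] is the parent node id of node i (-1 for the root);
    length[i] is the length of the branch above node i (0.0 for the root);
    label[i] is the taxon label for leaves (mandatory, unique) and an
    optional label for internal nodes (may be None).
    """

    parent: list[int]
    length: list[float]
    label: list[str | None]
    root: int = 0
    children: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.parent)
        if not (len(self.length) == len(self.label) == n):
            raise ValueError("parent/length/label arrays must have equal size")
        roots = [i for i, p in enumerate(self.parent) if p == -1]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        if any(t < 0 for t in self.length):
            raise ValueError("branch lengths must be non-negative")
        self.children = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        leaf_labels = [self.label[i] for i in self.leaves()]
        if any(lb is None for lb in leaf_labels):
            raise ValueError("every leaf must carry a taxon label")
        if len(set(leaf_labels)) != len(leaf_labels):
            dupes = sorted({x for x in leaf_labels if leaf_labels.count(x) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        # connectivity/acyclicity: walking up from every node must reach the root
        for i in range(n):
            seen, j = 0, i
            while self.parent[j] != -1:
                j = self.parent[j]
                seen += 1
                if seen > n:
                    raise ValueError("parent links contain a cycle")

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def taxa(self) -> list[str]:
        return [self.label[i] for i in self.leaves()]  # type: ignore[misc]

    def branches(self) -> list[int]:
        """Branch ids = child-node ids of every branch (all non-root nodes)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def leaf_by_label(self) -> dict[str, int]:
        return {self.label[i]: i for i in self.leaves()}  # type: ignore[misc]

    def leafset_below(self, node: int) -> frozenset[str]:
        out: list[str] = []
        stack = [node]
        while stack:
            j = stack.pop()
            if self.is_leaf(j):
                out.append(self.label[j])  # type: ignore[arg-type]
            else:
                stack.extend(self.children[j])
        return frozenset(out)

    def mrca(self, taxa: set[str]) -> int:
        """Most recent common ancestor of a set of taxon labels."""
        by_label = self.leaf_by_label()
        missing = sorted(set(taxa) - by_label.keys())
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        paths = []
        for t in taxa:
            path, j = [], by_label[t]
            while j != -1:
                path.append(j)
                j = self.parent[j]
            paths.append(path[::-1])
        k = 0
        while all(len(p) > k for p in paths) and len({p[k] for p in paths}) == 1:
            k += 1
        return paths[0][k - 1]

    def depths(self) -> list[float]:
        """Root-to-node path lengths."""
        out = [0.0] * self.n_nodes
        for i in self.postorder()[::-1]:
            if self.parent[i] != -1:
                out[i] = out[self.parent[i]] + self.length[i]
        return out

    # -- Newick ----------------------------------------------------------

    def write_newick(self, label_fn=None) -> str:
        """Serialize to Newick.  Branch lengths use repr (full precision).

        label_fn(node_id) may override node labels, e.g. for annotated output.
        """

        def fmt(node: int) -> str:
            lab = label_fn(node) if label_fn is not None else self.label[node]
            lab = "" if lab is None else str(lab)
            if lab and any(c in lab for c in "(),:; '\t"):
                lab = "'" + lab.replace("'", "''") + "'"
            if self.is_leaf(node):
                body = lab
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[node]) + ")" + lab
            if node == self.root:
                return body
            return f"{body}:{self.length[node]!r}"

        return fmt(self.root) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Supports quoted and unquoted labels, internal-node labels, and decimal
    or scientific-notation branch lengths.  Malformed input raises
    :class:`NewickError` naming the offending character position.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError(f"missing ';' terminator at position {len(s)}")
    s = s[:-1]
    parent: list[int] = []
    length: list[float] = []
    label: list[str | None] = []

    def new_node(par: int) -> int:
        parent.append(par)
        length.append(0.0)
        label.append(None)
        return len(parent) - 1

    pos = 0
    n = len(s)

    def err(msg: str) -> NewickError:
        return NewickError(f"{msg} at position {pos}")

    def read_label() -> str | None:
        nonlocal pos
        if pos < n and s[pos] == "'":
            end = s.find("'", pos + 1)
            if end == -1:
                raise err("unterminated quoted label")
            out = s[pos + 1 : end]
            pos = end + 1
            return out
        start = pos
        while pos < n and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos] or None

    def read_length(node: int) -> None:
        nonlocal pos
        if pos < n and s[pos] == ":":
            pos += 1
            start = pos
            while pos < n and (s[pos].isdigit() or s[pos] in ".+-eE"):
                pos += 1
            try:
                length[node] = float(s[start:pos])
            except ValueError:
                raise err(f"invalid branch length {s[start:pos]!r}") from None

    def read_clade(par: int) -> int:
        nonlocal pos
        node = new_node(par)
        if pos < n and s[pos] == "(":
            pos += 1
            while True:
                read_clade(node)
                if pos >= n:
                    raise err("unbalanced parentheses: unexpected end")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise err(f"unexpected character {s[pos]!r}")
        label[node] = read_label()
        read_length(node)
        return node

    read_clade(-1)
    if pos != n:
        raise NewickError(f"trailing characters at position {pos}")
    tree = PhyloTree(parent=parent, length=length, label=label)
    if tree.length[tree.root] != 0.0:
        tree.length[tree.root] = 0.0  # root branch length is meaningless
    return tree


# -- branch classes ------------------------------------------------------

SCHEMES = ("homogeneous", "M1", "M2", "terminal_clades", "per_branch")


@dataclass
class BranchClassMap:
    """Partition of a tree's branches into contiguous integer classes."""

    branch_class: dict[int, int]
    n_classes: int
    class_names: list[str]

    def __post_init__(self) -> None:
        seen = set(self.branch_class.values())
        if seen and (min(seen) != 0 or max(seen) != self.n_classes - 1):
            raise ValueError("class ids must be contiguous from 0")

    def refines(self, coarser: "BranchClassMap") -> bool:
        """True if every class of `coarser` is a union of classes of self."""
        if set(self.branch_class) != set(coarser.branch_class):
            return False
        fine_to_coarse: dict[int, int] = {}
        for b, f in self.branch_class.items():
            c = coarser.branch_class[b]
            if fine_to_coarse.setdefault(f, c) != c:
                return False
        return True


def check_monophyly(tree: PhyloTree, name: str, taxa: set[str]) -> int:
    """Return the MRCA of `taxa`, or raise if the clade is not monophyletic."""
    node = tree.mrca(taxa)
    below = set(tree.leafset_below(node))
    extra = sorted(below - taxa)
    if extra:
        raise ValueError(
            f"clade {name!r} is not monophyletic: MRCA also contains {extra}"
        )
    return node


def assign_branch_classes(
    tree: PhyloTree,
    scheme: str,
    clade_defs: dict[str, set[str]] | None = None,
) -> BranchClassMap:
    """Map every branch of `tree` to a model class under `scheme`.

    homogeneous: one class.  per_branch: one class per branch.  Clade
    schemes (M1/M2/terminal_clades): one class per named group; a branch
    whose descendant leaves all belong to one group takes that group's
    class (this covers each group's stem branch); a backbone branch whose
    descendants span several groups takes the class of the earliest-listed
    group below it, so every branch is classified deterministically.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    branches = tree.branches()
    if scheme == "homogeneous":
        return BranchClassMap({b: 0 for b in branches}, 1, ["all"])
    if scheme == "per_branch":
        return BranchClassMap(
            {b: k for k, b in enumerate(branches)},
            len(branches),
            [f"branch_{b}" for b in branches],
        )
    if not clade_defs:
        raise ValueError(f"scheme {scheme!r} requires clade definitions")
    names = list(clade_defs)
    taxon_to_class: dict[str, int] = {}
    for k, name in enumerate(names):
        check_monophyly(tree, name, clade_defs[name])
        for t in clade_defs[name]:
            if t in taxon_to_class:
                raise ValueError(f"taxon {t!r} listed in more than one clade")
            taxon_to_class[t] = k
    uncovered = sorted(set(tree.taxa()) - taxon_to_class.keys())
    if uncovered:
        raise ValueError(f"taxa not covered by any clade: {uncovered}")
    bc: dict[int, int] = {}
    for b in branches:
        classes_below = {taxon_to_class[t] for t in tree.leafset_below(b)}
        bc[b] = min(classes_below)
    return BranchClassMap(bc, len(names), names)


# -- tree transforms -----------------------------------------------------


def prune_to_taxa(tree: PhyloTree, taxa: set[str]) -> PhyloTree:
    """Restrict a tree to a subset of its taxa.

    Unsampled leaves are dropped, degree-2 internal nodes are suppressed
    (their branch lengths add), and the root is re-seated at the MRCA of
    the kept taxa.
    """
    keep_leaves = {i for i in tree.leaves() if tree.label[i] in taxa}
    if len(keep_leaves) != len(taxa & set(tree.taxa())):
        pass  # label->leaf is unique, so this cannot diverge
    if len(keep_leaves) < 2:
        raise ValueError("pruning needs at least two kept taxa")
    # nodes with at least one kept leaf below
    keep: set[int] = set()
    for leaf in keep_leaves:
        j = leaf
        while j != -1 and j not in keep:
            keep.add(j)
            j = tree.parent[j]
    new_parent: list[int] = []
    new_length: list[float] = []
    new_label: list[str | None] = []

    def build(node: int, par: int, carry: float) -> None:
        kids = [c for c in tree.children[node] if c in keep]
        if node in keep_leaves or len(kids) >= 2:
            idx = len(new_parent)
            new_parent.append(par)
            new_length.append(carry + tree.length[node] if par != -1 else 0.0)
            new_label.append(tree.label[node])
            for c in kids:
                build(c, idx, 0.0)
        elif len(kids) == 1:  # suppress unifurcation
            build(kids[0], par, carry + (tree.length[node] if par != -1 else 0.0))
        else:
            raise AssertionError("unreachable: kept node with no kept children")

    # new root = deepest node with >=2 kept children (MRCA of kept taxa)
    start = tree.root
    while True:
        kids = [c for c in tree.children[start] if c in keep]
        if len(kids) == 1 and start not in keep_leaves:
            start = kids[0]
        else:
            break
    build(start, -1, 0.0)
    return PhyloTree(parent=new_parent, length=new_length, label=new_label)


def with_unit_lengths(tree: PhyloTree) -> PhyloTree:
    """Copy of the tree with every branch length set to 1."""
    return PhyloTree(
        parent=list(tree.parent),
        length=[0.0 if p == -1 else 1.0 for p in tree.parent],
        label=list(tree.label),
    )


def resolve_polytomies(tree: PhyloTree, eps: float = 1e-8) -> PhyloTree:
    """Binary version of the tree: multifurcations are resolved
    arbitrarily (left-ladderized) with `eps`-length branches so that
    contrast covariance matrices stay nonsingular."""
    parent = list(tree.parent)
    length = list(tree.length)
    label: list[str | None] = list(tree.label)
    children = [list(c) for c in tree.children]
    i = 0
    while i < len(parent):
        while len(children[i]) > 2:
            extra = children[i][1:]
            new = len(parent)
            parent.append(i)
            length.append(eps)
            label.append(None)
            children.append(extra)
            for c in extra:
                parent[c] = new
            children[i] = [children[i][0], new]
        i += 1
    return PhyloTree(parent=parent, length=length, label=label)


def read_clade_defs(text: str) -> dict[str, set[str]]:
    """Parse clade definitions from TSV lines of (clade_name, taxon)."""
    out: dict[str, set[str]] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"clade TSV line {ln}: expected 2 columns, got {len(parts)}")
        out.setdefault(parts[0], set()).add(parts[1])
    return out
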