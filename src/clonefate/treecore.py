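"""Tree data model and branch-level operations for somatic phylogenies.

The central object is :class:`Phylogeny`: a rooted tree over single-cell-derived
colonies in which every branch length counts somatic SNVs ("molecular time") or
years.  The zygote sits at the root, so node depth measures mutational (or
chronological) distance from conception.  Branches carry the mutations assigned
to them; leaves carry a donor/recipient origin flag so a single combined tree
can describe both sides of a transplant pair.

Operations provided here:

* newick round-trip I/O (dendropy does the parsing);
* maximum-likelihood assignment of mutations to branches from read counts;
* sensitivity-based branch-length correction (private and shared branches);
* Monte-Carlo estimation of somatic variant sensitivity for impure colonies;
* conversion of a molecular-time tree to an ultrametric time tree;
* negative-binomial branch-length bootstrapping;
* cutting the tree at a molecular-time height to define clones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "Phylogeny",
    "SensitivityProfile",
    "Clone",
    "NewickError",
    "read_newick",
    "write_newick",
    "assign_mutations_to_branches",
    "correct_branch_lengths",
    "somatic_sensitivity",
    "prepare_time_tree",
    "bootstrap_branch_lengths",
    "cut_tree_clones",
]


class NewickError(ValueError):
    """Raised when a newick string cannot be parsed or validated."""


class Node:
    """A tree node; its ``length`` is the branch connecting it to its parent."""

    __slots__ = ("name", "length", "parent", "children", "origin", "mutations")

    def __init__(self, name, length=0.0, origin=None):
        self.name = name
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.origin: str | None = origin  # 'donor' | 'recipient' | None
        self.mutations: list[str] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length:g}, leaf={self.is_leaf})"


class Phylogeny:
    """Rooted phylogeny with branch lengths in ``unit`` ('mutations' or 'years').

    Invariants enforced at construction: exactly one root, unique node names,
    non-negative branch lengths.
    """

    VALID_UNITS = ("mutations", "years")

    def __init__(self, root: Node, unit: str = "mutations", meta: dict | None = None):
        if unit not in self.VALID_UNITS:
            raise ValueError(f"unit must be one of {self.VALID_UNITS}, got {unit!r}")
        self.root = root
        self.unit = unit
        self.meta: dict = dict(meta or {})
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.preorder():
            if node.name in seen:
                raise NewickError(f"duplicate node label {node.name!r}")
            seen.add(node.name)
            if node.length < 0:
                raise ValueError(f"negative branch length on {node.name!r}")
        if self.root.parent is not None:
            raise ValueError("root must not have a parent")

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def branches(self) -> list[Node]:
        """All nodes that have a parent branch (every node except the root)."""
        return [n for n in self.preorder() if n.parent is not None]

    def node(self, name: str) -> Node:
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def depths(self) -> dict[Node, float]:
        """Distance of each node from the root (root depth 0)."""
        depth = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depth[node] = depth[node.parent] + node.length
        return depth

    def clade_leaves(self, node: Node) -> list[Node]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            stack.extend(n.children)
        return out

    def copy(self) -> "Phylogeny":
        mapping: dict[Node, Node] = {}
        for node in self.preorder():
            clone = Node(node.name, node.length, node.origin)
            clone.mutations = list(node.mutations)
            mapping[node] = clone
            if node.parent is not None:
                mapping[node.parent].add_child(clone)
        return Phylogeny(mapping[self.root], unit=self.unit, meta=dict(self.meta))

    # -- derived quantities ------------------------------------------------
    def cophenetic(self) -> tuple[list[str], np.ndarray]:
        """Pairwise patristic distances between leaves.

        Returns the leaf-name order and the symmetric distance matrix.
        """
        depth = self.depths()
        leaves = self.leaves()
        index = {leaf: i for i, leaf in enumerate(leaves)}
        dist = np.zeros((len(leaves), len(leaves)))
        # leaf sets bottom-up; pairs split at their MRCA
        leafset: dict[Node, list[Node]] = {}
        for node in self.postorder():
            if node.is_leaf:
                leafset[node] = [node]
            else:
                sets = [leafset.pop(c) for c in node.children]
                for i in range(len(sets)):
                    for j in range(i + 1, len(sets)):
                        for a in sets[i]:
                            for b in sets[j]:
                                d = depth[a] + depth[b] - 2.0 * depth[node]
                                dist[index[a], index[b]] = d
                                dist[index[b], index[a]] = d
                merged = [leaf for s in sets for leaf in s]
                leafset[node] = merged
        return [l.name for l in leaves], dist

    def shared_branches(self) -> set[Node]:
        """Branches ancestral to both a donor leaf and a recipient leaf."""
        shared: set[Node] = set()
        origins: dict[Node, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                origins[node] = {node.origin} if node.origin else set()
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= origins[c]
                origins[node] = acc
            if node.parent is not None and {"donor", "recipient"} <= origins[node]:
                shared.add(node)
        return shared

    def __len__(self) -> int:
        return sum(1 for _ in self.preorder())


@dataclass
class SensitivityProfile:
    """Per-colony variant-calling sensitivities.

    ``somatic_sensitivity`` maps sample name to the probability p_i in (0, 1]
    that a true heterozygous somatic SNV in that colony is called; ``peak_vaf``
    is the mode of the colony's VAF density (a purity proxy).
    """

    somatic_sensitivity: dict[str, float]
    peak_vaf: dict[str, float] = field(default_factory=dict)
    germline_snv_sensitivity: dict[str, float] = field(default_factory=dict)
    germline_indel_sensitivity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for s, p in self.somatic_sensitivity.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"sensitivity for {s!r} must be in (0, 1], got {p}")


@dataclass
class Clone:
    """A clone defined by a branch crossing the molecular-time cut."""

    name: str
    node: Node  # the child end of the branch spanning the cut
    leaves: list[Node]

    @property
    def size(self) -> int:
        return len(self.leaves)


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree, unit: str) -> Phylogeny:
    counter = [0]

    def build(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        if label is None:
            counter[0] += 1
            label = f"internal_{counter[0]}"
        node = Node(label, dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add_child(build(child))
        return node

    return Phylogeny(build(dtree.seed_node), unit=unit)


def read_newick(source, unit: str = "mutations") -> Phylogeny:
    """Read a rooted tree from a newick file path or string.

    Unlabeled internal nodes are auto-labelled ``internal_<k>`` in preorder, so
    repeated reads of the same string produce identical labels.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "(" not in text:  # looks like a path
            with open(text) as fh:
                text = fh.read()
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error classes
        offset = text.find(";")
        raise NewickError(
            f"malformed newick (near byte offset {max(offset, 0)}): {exc}"
        ) from exc
    return _from_dendropy(dtree, unit)


def _to_newick(node: Node) -> str:
    if node.is_leaf:
        body = node.name
    else:
        body = "(" + ",".join(_to_newick(c) for c in node.children) + ")" + node.name
    if node.parent is None:
        return body
    return f"{body}:{node.length:.12g}"


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialise to newick; returns the string and optionally writes a file."""
    text = _to_newick(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------------
# mutation assignment
# ---------------------------------------------------------------------------

def assign_mutations_to_branches(
    tree: Phylogeny,
    counts,
    epsilon: float = 0.01,
    purity: dict[str, float] | None = None,
) -> dict[str, list[str]]:
    """Assign each mutation to the branch maximising a binomial likelihood.

    For a candidate branch the expected VAF is ``0.5 * purity`` in every
    descendant leaf and ``epsilon`` elsewhere; the branch with the highest
    summed binomial log-likelihood over colonies wins.  Mutations with zero
    depth everywhere are flagged unassignable and excluded.

    Parameters
    ----------
    counts:
        A :class:`~clonefate.readcounts.ReadCountMatrix` whose samples include
        every leaf of ``tree``.
    Returns
    -------
    dict mapping branch (node) name -> list of mutation ids.  Mutations are
    also recorded on ``node.mutations``.
    """
    leaves = tree.leaves()
    sample_names = [l.name for l in leaves]
    missing = set(sample_names) - set(counts.samples)
    if missing:
        raise ValueError(f"tree leaves missing from count matrix: {sorted(missing)}")
    var = counts.variant_matrix(sample_names)   # (n_mut, n_samples)
    dep = counts.depth_matrix(sample_names)
    mut_ids = list(counts.mutations)

    purity = purity or {}
    pur = np.array([purity.get(s, 1.0) for s in sample_names])

    branch_nodes = tree.branches()
    # membership[b, s] = 1 if leaf s descends from branch b
    membership = np.zeros((len(branch_nodes), len(sample_names)))
    leaf_index = {name: i for i, name in enumerate(sample_names)}
    for bi, bnode in enumerate(branch_nodes):
        for leaf in tree.clade_leaves(bnode):
            membership[bi, leaf_index[leaf.name]] = 1.0

    p = membership * (0.5 * pur) + (1.0 - membership) * epsilon
    p = np.clip(p, 1e-12, 1 - 1e-12)
    # (n_mut, n_branch): Y log p + (N - Y) log(1 - p), binomial coefficient constant
    loglik = var @ np.log(p).T + (dep - var) @ np.log1p(-p).T

    assignment: dict[str, list[str]] = {b.name: [] for b in branch_nodes}
    informative = dep.sum(axis=1) > 0
    best = np.argmax(loglik, axis=1)
    n_unassignable = 0
    for mi, mut in enumerate(mut_ids):
        if not informative[mi]:
            n_unassignable += 1
            continue
        bnode = branch_nodes[best[mi]]
        assignment[bnode.name].append(mut)
        bnode.mutations.append(mut)
    if n_unassignable:
        warnings.warn(f"{n_unassignable} mutation(s) with zero depth everywhere "
                      "were flagged unassignable and excluded")
    return assignment


# ---------------------------------------------------------------------------
# branch-length correction
# ---------------------------------------------------------------------------

def correct_branch_lengths(tree: Phylogeny, profile: SensitivityProfile) -> Phylogeny:
    """Scale branch lengths for imperfect variant-calling sensitivity.

    Private (terminal) branches are divided by that colony's somatic variant
    sensitivity p_i.  Shared branches are divided by ``1 - prod(1 - p_i)`` over
    the colonies of the clade: a shared mutation is missed only if it is missed
    in every colony carrying it.  Corrected lengths are always >= raw lengths.
    """
    out = tree.copy()
    p = profile.somatic_sensitivity
    for leaf in out.leaves():
        if leaf.name not in p:
            raise ValueError(f"no sensitivity for leaf {leaf.name!r}")
    for node in out.preorder():
        if node.parent is None:
            continue
        clade = out.clade_leaves(node)
        if node.is_leaf:
            node.length = node.length / p[node.name]
        else:
            miss = 1.0
            for leaf in clade:
                miss *= 1.0 - p[leaf.name]
            node.length = node.length / (1.0 - miss)
    return out


def somatic_sensitivity(
    germline_sensitivity: float,
    peak_vaf: float,
    depth_distribution: Sequence[int],
    sensitivity_matrix: np.ndarray | Callable[[int, int], float],
    seed: int | None = None,
    clonal_peak_threshold: float = 0.48,
) -> float:
    """Somatic variant sensitivity, with a clonality correction for impure colonies.

    Colonies with a VAF-density peak above ``clonal_peak_threshold`` (purity
    > 96%) keep their germline sensitivity.  For less pure colonies, the
    expected variant reads for a heterozygous somatic mutation are
    ``n_v ~ Binomial(N, peak_vaf)``; the probability that such a site is called
    is looked up in ``sensitivity_matrix`` (indexed ``[n_v, N]`` or a callable)
    and the Monte-Carlo mean call rate over the germline-site depth
    distribution is returned.
    """
    depths = np.asarray(depth_distribution, dtype=int)
    if depths.size == 0:
        raise ValueError("empty depth distribution")
    if not (0.0 < peak_vaf <= 0.6):
        raise ValueError(f"peak_vaf must be in (0, 0.6], got {peak_vaf}")
    if peak_vaf > clonal_peak_threshold:
        return float(germline_sensitivity)
    rng = np.random.default_rng(seed)
    n_v = rng.binomial(depths, peak_vaf)
    if callable(sensitivity_matrix):
        call_p = np.array([sensitivity_matrix(v, n) for v, n in zip(n_v, depths)])
    else:
        m = np.asarray(sensitivity_matrix)
        vi = np.clip(n_v, 0, m.shape[0] - 1)
        ni = np.clip(depths, 0, m.shape[1] - 1)
        call_p = m[vi, ni]
    called = rng.random(depths.size) < call_p
    return float(called.mean())


# ---------------------------------------------------------------------------
# time trees
# ---------------------------------------------------------------------------

def make_ultrametric(tree: Phylogeny, tol: float = 1e-6, max_iter: int = 100) -> Phylogeny:
    """Iteratively-reweighted-means ultrametric-isation.

    Each iteration computes root-to-tip distances, then rescales every branch by
    the mean of ``target/d_leaf`` over the leaves that share it — shared
    branches average over more leaves and so move less, reflecting the greater
    confidence in branch lengths supported by many colonies.  Iterates to
    relative tolerance ``tol``; a final exact adjustment of terminal branches
    removes residual rounding so the result is idempotent.
    """
    out = tree.copy()
    leaves = out.leaves()
    if not leaves:
        return out
    for _ in range(max_iter):
        depth = out.depths()
        d = np.array([depth[l] for l in leaves])
        target = d.mean()
        if target <= 0:
            break
        if np.max(np.abs(d / target - 1.0)) < tol:
            break
        ratio = {l: target / max(depth[l], 1e-12) for l in leaves}
        for node in out.postorder():
            if node.parent is None:
                continue
            clade = out.clade_leaves(node)
            m = sum(ratio[l] for l in clade) / len(clade)
            node.length *= m
    # exact clean-up on terminal branches (residuals are < tol * height)
    depth = out.depths()
    d = np.array([depth[l] for l in leaves])
    target = d.mean()
    n_clipped = 0
    for leaf, dl in zip(leaves, d):
        new = leaf.length + (target - dl)
        if new < 0:
            n_clipped += 1
            new = 0.0
        leaf.length = new
    if n_clipped:
        warnings.warn(f"{n_clipped} terminal branch(es) clipped to 0 during "
                      "ultrametric-isation")
    out.meta["ultrametric"] = True
    return out


def prepare_time_tree(
    tree: Phylogeny,
    rate_per_year: float = 15.8,
    birth_burden: float = 60.0,
    terminal_shortening: float = 60.0,
    sporadic_fractions: dict[str, float] | None = None,
    sampling_age: float | None = None,
) -> Phylogeny:
    """Convert a molecular-time phylogeny into an ultrametric time tree.

    Steps: (1) subtract per-branch sporadic-signature mutation counts (platinum,
    APOBEC — bursts unlinked to time); (2) shorten terminal branches by
    ``terminal_shortening`` mutations (in vitro plus differentiation-associated
    mutations; floored at 0); (3) ultrametric-ise with the iteratively
    reweighted means algorithm; (4) map molecular height to age so that the
    first ``birth_burden`` mutations correspond to birth and the tips sit at
    ``sampling_age`` years.
    """
    if rate_per_year <= 0:
        raise ValueError("rate_per_year must be positive")
    out = tree.copy()
    n_clipped = 0
    sporadic = sporadic_fractions or {}
    for node in out.preorder():
        if node.parent is None:
            continue
        length = node.length - sporadic.get(node.name, 0.0)
        if node.is_leaf:
            length -= terminal_shortening
        if length < 0:
            n_clipped += 1
            length = 0.0
        node.length = length
    if n_clipped:
        warnings.warn(f"{n_clipped} branch(es) clipped to 0 after burden subtraction")
    out = make_ultrametric(out)
    depth = out.depths()
    height = np.mean([depth[l] for l in out.leaves()])
    if sampling_age is None:
        sampling_age = max(height - birth_burden, 0.0) / rate_per_year
    denom = max(height - birth_burden, 1e-12)
    # node ages from node heights: development (first birth_burden mutations)
    # is compressed to age 0, the remainder scales linearly to sampling_age
    age = {n: sampling_age * max(depth[n] - birth_burden, 0.0) / denom
           for n in out.preorder()}
    for node in out.preorder():
        if node.parent is not None:
            node.length = max(age[node] - age[node.parent], 0.0)
    out.unit = "years"
    out.meta["sampling_age"] = float(sampling_age)
    out.meta["ultrametric"] = True
    return out


def bootstrap_branch_lengths(
    tree: Phylogeny, theta: float, n_boot: int, seed: int | None = None
) -> list[Phylogeny]:
    """Redraw every branch length from NegBinom(mean=original, dispersion=theta).

    ``theta`` is the overdispersion of the mutation-burden distribution; as
    theta -> infinity the redraws approach Poisson(original).  Topology is
    preserved; a fixed seed gives identical output.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_boot):
        t = tree.copy()
        for node in t.preorder():
            if node.parent is None:
                continue
            mu = node.length
            if mu <= 0:
                node.length = 0.0
                continue
            p = theta / (theta + mu)
            node.length = float(rng.negative_binomial(theta, p))
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# clone cutting
# ---------------------------------------------------------------------------

def cut_tree_clones(tree: Phylogeny, cut_height: float) -> list[Clone]:
    """Cut the tree at a molecular-time height (distance from the root/zygote).

    Every branch whose span ``(parent_depth, node_depth]`` contains
    ``cut_height`` founds one clone containing its descendant leaves, so clones
    originate exactly at the cut.  A non-positive cut, or a cut above all tips,
    yields a single clone holding the whole tree.  Leaves shallower than the
    cut (possible in non-ultrametric trees) become singleton clones.
    """
    depth = tree.depths()
    leaves = tree.leaves()
    max_tip = max(depth[l] for l in leaves)
    if cut_height <= 0:
        return [Clone("clone_all", tree.root, leaves)]
    if cut_height > max_tip:
        warnings.warn("cut height above all tips; returning a single clone")
        return [Clone("clone_all", tree.root, leaves)]
    clones: list[Clone] = []
    assigned: set[Node] = set()
    for node in tree.preorder():
        if node.parent is None:
            continue
        lo, hi = depth[node.parent], depth[node]
        if lo < cut_height <= hi:
            members = tree.clade_leaves(node)
            clones.append(Clone(f"clone_{node.name}", node, members))
            assigned.update(members)
    for leaf in leaves:  # leaves entirely below the cut
        if leaf not in assigned:
            clones.append(Clone(f"clone_{leaf.name}", leaf, [leaf]))
    return clones
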