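"""Distance-based clustering and monophyly checks.

Neighbor-joining (Saitou & Nei) from a pairwise distance matrix, a
column-resampling bootstrap over the underlying alignment, and
per-species monophyly verdicts on the outgroup-rooted tree.  This is a
deliberate distance-based surrogate for likelihood/Bayesian tree
inference: the question it answers — do conspecific barcodes cluster
together with high support? — only needs bipartitions, not branch-length
optimality.

Determinism: agglomeration ties on the Q criterion are broken
lexicographically on node labels, so a tree depends only on the matrix.
Negative branch-length estimates are clamped to zero and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitobarcode.barcode_stats import DistanceMatrix, distance_matrix
from mitobarcode.seqio import Alignment, SequenceRecord


@dataclass
class TreeNode:
    label: str                      # tip label, or internal id
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0             # branch to parent
    support: float | None = None    # bootstrap %, internal edges only

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list[str]:
        if self.is_tip:
            return [self.label]
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.tips())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary trifurcating root node."""

    root: TreeNode
    clamped_negative: int = 0  # NJ branch estimates clamped to 0

    def tips(self) -> list[str]:
        return self.root.tips()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized to the side not
        containing the lexicographically smallest tip."""
        all_tips = frozenset(self.tips())
        anchor = min(all_tips)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> None:
            for ch in node.children:
                side = frozenset(ch.tips())
                if anchor in side:
                    side = all_tips - side
                if 1 < len(side) < len(all_tips) - 1:
                    splits.add(side)
                walk(ch)

        walk(self.root)
        return splits

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                return f"{_quote(node.label)}:{node.length:.6f}"
            inner = ",".join(fmt(ch) for ch in node.children)
            sup = ""
            if with_support and node.support is not None:
                sup = f"{node.support:.0f}"
            return f"({inner}){sup}:{node.length:.6f}"

        inner = ",".join(fmt(ch) for ch in self.root.children)
        return f"({inner});"


def _quote(label: str) -> str:
    if any(c in label for c in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# neighbor-joining


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor-joining with the Q criterion.

    Requires >= 3 taxa and finite distances (undefined entries raise,
    listing the offending pairs).  On an additive matrix the returned
    tree's path metric reproduces the input exactly.
    """
    undef = dm.undefined_pairs()
    if undef:
        raise ValueError(f"undefined distances for pairs: {undef}")
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")

    nodes: dict[str, TreeNode] = {i: TreeNode(i) for i in dm.ids}
    d: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = dm.ids[i], dm.ids[j]
            d[(a, b)] = d[(b, a)] = float(dm.d[i, j])
    active = sorted(dm.ids)
    clamped = 0
    internal_counter = 0

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else d[(a, b)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active) for a in active}
        best: tuple[float, str, str] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)  # lexicographic tie-break on labels
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        if la < 0:
            clamped += 1
            lb = min(dab, lb - la)  # transfer, preserving the path length
            la = 0.0
        if lb < 0:
            clamped += 1
            la = min(dab, la - lb)
            lb = 0.0
        internal_counter += 1
        new_label = f"__nj{internal_counter}"
        parent = TreeNode(new_label)
        nodes[a].length = la
        nodes[b].length = lb
        parent.children = [nodes[a], nodes[b]]
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[(new_label, c)] = d[(c, new_label)] = duc
        active = sorted([c for c in active if c not in (a, b)] + [new_label])

    # terminal trifurcation
    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    for node_label, length in ((a, la), (b, lb), (c, lc)):
        if length < 0:
            clamped += 1
            length = 0.0
        nodes[node_label].length = length
    root = TreeNode("__root", children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root, clamped_negative=clamped)


def path_metric(tree: Tree) -> dict[tuple[str, str], float]:
    """Tip-to-tip path lengths of a tree (for additivity checks)."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_tip:
            return {node.label: 0.0}
        below: list[dict[str, float]] = []
        for ch in node.children:
            sub = {t: dl + ch.length for t, dl in walk(ch).items()}
            below.append(sub)
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for t1, d1 in below[i].items():
                    for t2, d2 in below[j].items():
                        key = (min(t1, t2), max(t1, t2))
                        dists[key] = d1 + d2
        merged: dict[str, float] = {}
        for sub in below:
            merged.update(sub)
        return merged

    walk(tree.root)
    return dists


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    aln: Alignment,
    reps: int = 1000,
    seed: int = 0,
    model: str = "K2P",
) -> Tree:
    """NJ tree with column-resampling bootstrap supports.

    Resamples alignment columns with replacement, rebuilds the NJ tree
    per replicate, and scores each original bipartition by the
    percentage of replicates containing it.  Replicates whose resampled
    matrix has undefined distances are redrawn (counted up to a bound).
    """
    if reps < 1:
        raise ValueError("bootstrap needs at least 1 replicate")
    dm = distance_matrix(aln, model)
    tree = nj_tree(dm)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = aln.length
    done = 0
    attempts = 0
    while done < reps:
        attempts += 1
        if attempts > 10 * reps:
            raise RuntimeError("too many bootstrap replicates with undefined distances")
        cols = rng.integers(0, L, size=L)
        recs = [SequenceRecord(id=r.id, seq="".join(r.seq[j] for j in cols),
                               species=r.species) for r in aln.records]
        bdm = distance_matrix(Alignment(recs), model)
        if bdm.undefined_pairs():
            continue
        bt = nj_tree(bdm)
        reps_bps = bt.bipartitions()
        for bp in target:
            if bp in reps_bps:
                counts[bp] += 1
        done += 1

    def annotate(node: TreeNode) -> None:
        for ch in node.children:
            if not ch.is_tip:
                all_tips = frozenset(tree.tips())
                side = frozenset(ch.tips())
                if min(all_tips) in side:
                    side = all_tips - side
                if 1 < len(side) < len(all_tips) - 1:
                    ch.support = 100.0 * counts[side] / reps
            annotate(ch)

    annotate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# monophyly


def is_monophyletic(tree: Tree, tips: set[str], outgroup: str) -> bool:
    """True iff, after rooting on ``outgroup``, ``tips`` is exactly the
    tip set of some clade.

    Equivalent split formulation on the unrooted tree: the subset is a
    clade iff some edge separates exactly ``tips`` from everything else
    (outgroup included), or the subset is everything but the outgroup.
    """
    all_tips = set(tree.tips())
    tips = set(tips)
    unknown = (tips | {outgroup}) - all_tips
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    if outgroup in tips:
        raise ValueError("outgroup cannot be part of the query set")
    if len(tips) == 1 or tips == all_tips - {outgroup}:
        return True
    query = frozenset(tips)
    anchor = min(all_tips)
    canonical = frozenset(all_tips - query) if anchor in query else query
    return canonical in tree.bipartitions()


def clade_support(tree: Tree, tips: set[str]) -> float | None:
    """Bootstrap support of the edge subtending ``tips``; None if the
    clade is absent or the edge trivial."""
    all_tips = frozenset(tree.tips())
    query = frozenset(tips)
    anchor = min(all_tips)
    canonical = all_tips - query if anchor in query else query

    found: list[float | None] = []

    def walk(node: TreeNode) -> None:
        for ch in node.children:
            if not ch.is_tip:
                side = frozenset(ch.tips())
                if anchor in side:
                    side = all_tips - side
                if side == canonical:
                    found.append(ch.support)
            walk(ch)

    walk(tree.root)
    return found[0] if found else None


def monophyly_report(
    tree: Tree,
    labels: dict[str, str],
    outgroup: str,
) -> list[dict]:
    """Per-species verdicts: species, n tips, monophyletic, support."""
    rows = []
    for sp in sorted({s for t, s in labels.items() if t != outgroup}):
        tips = {t for t, s in labels.items() if s == sp and t != outgroup}
        verdict = is_monophyletic(tree, tips, outgroup)
        support = clade_support(tree, tips) if verdict and len(tips) > 1 else None
        rows.append({"species": sp, "n_tips": len(tips),
                     "monophyletic": verdict, "support": support})
    return rows
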