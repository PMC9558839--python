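"""Phylogeny container, Yule/birth-death simulators, Newick I/O and time queries.

Trees are rooted and time-calibrated; all likelihood code in this package
assumes contemporaneous (ultrametric) tips.  Nodes are integer-indexed with
parent pointers; the branch of a node is the edge connecting it to its
parent, so every non-root node carries exactly one branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "NewickError",
    "SimulationError",
    "read_newick",
    "write_newick",
    "shared_times",
    "simulate_yule",
    "simulate_birth_death",
]

_ULTRAMETRIC_RTOL = 1e-9
_MAX_REJECTIONS = 100_000


class NewickError(ValueError):
    """Raised for malformed Newick input."""


class SimulationError(RuntimeError):
    """Raised when a tree simulator exhausts its rejection budget."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in time units.

    Parameters
    ----------
    parent
        Integer array of parent indices; ``-1`` for the root.
    blen
        Branch length of the edge above each node (``0.0`` for the root).
    labels
        One entry per node; tip labels are required and unique, internal
        labels optional (``None``).
    root
        Index of the root node.
    """

    parent: np.ndarray
    blen: np.ndarray
    labels: list
    root: int = 0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        n = len(self.parent)
        if len(self.blen) != n or len(self.labels) != n:
            raise ValueError("parent, blen and labels must have equal length")
        if (self.parent == -1).sum() != 1 or self.parent[self.root] != -1:
            raise ValueError("tree must have exactly one root")
        if np.any(self.blen < 0):
            raise ValueError("branch lengths must be non-negative")
        tips = self.tip_labels
        if any(lab is None for lab in tips):
            raise ValueError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            raise ValueError("tip labels must be unique")

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def children(self) -> list:
        if "children" not in self._cache:
            ch: list = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._cache["children"] = ch
        return self._cache["children"]

    @property
    def tips(self) -> np.ndarray:
        """Indices of tip nodes, in preorder."""
        if "tips" not in self._cache:
            ch = self.children
            self._cache["tips"] = np.array(
                [i for i in self.preorder() if not ch[i]], dtype=int
            )
        return self._cache["tips"]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tips]

    def preorder(self) -> list:
        if "preorder" not in self._cache:
            order, stack = [], [self.root]
            ch = self.children
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(reversed(ch[v]))
            self._cache["preorder"] = order
        return self._cache["preorder"]

    def postorder(self) -> list:
        return list(reversed(self.preorder()))

    # -- time geometry ---------------------------------------------------
    @property
    def node_times(self) -> np.ndarray:
        """Time of each node above the root (root at 0)."""
        if "node_times" not in self._cache:
            t = np.zeros(self.n_nodes)
            for v in self.preorder():
                p = self.parent[v]
                if p >= 0:
                    t[v] = t[p] + self.blen[v]
            self._cache["node_times"] = t
        return self._cache["node_times"]

    @property
    def height(self) -> float:
        return float(self.node_times[self.tips].max())

    @property
    def is_ultrametric(self) -> bool:
        depths = self.node_times[self.tips]
        h = depths.max()
        return bool(h == 0 or np.all(np.abs(depths - h) <= _ULTRAMETRIC_RTOL * h))

    def rescaled(self, height: float = 1.0) -> "Phylogeny":
        """Return a copy with all branch lengths scaled so the height is `height`."""
        h = self.height
        if h <= 0:
            raise ValueError("cannot rescale a tree of zero height")
        return Phylogeny(self.parent.copy(), self.blen * (height / h),
                         list(self.labels), self.root)

    def mrca(self, i: int, j: int) -> int:
        anc = set()
        v = i
        while v != -1:
            anc.add(v)
            v = self.parent[v]
        v = j
        while v not in anc:
            v = self.parent[v]
        return v


def shared_times(tree: Phylogeny) -> tuple:
    """Matrix of root-to-MRCA times for every tip pair.

    Returns ``(S, tip_labels)`` with ``S[i, j]`` the time from the root to
    the most recent common ancestor of tips i and j, and ``S[i, i]`` the
    root-to-tip time.  This is the Brownian-motion covariance kernel of the
    tree (up to the rate), and the ingredient of the OU covariance.
    """
    times = tree.node_times
    tips = tree.tips
    n = len(tips)
    tip_pos = {v: k for k, v in enumerate(tips)}
    S = np.zeros((n, n))
    S[np.diag_indices(n)] = times[tips]
    # tips descending from each internal node, grouped by child subtree:
    # pairs split across two subtrees coalesce exactly at that node.
    below: dict = {int(v): [int(v)] if not tree.children[v] else [] for v in range(tree.n_nodes)}
    for v in tree.postorder():
        ch = tree.children[v]
        if not ch:
            continue
        groups = [below[c] for c in ch]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for ti in groups[a]:
                    for tj in groups[b]:
                        ii, jj = tip_pos[ti], tip_pos[tj]
                        S[ii, jj] = S[jj, ii] = times[v]
        below[v] = [t for g in groups for t in g]
    return S, tree.tip_labels


# ---------------------------------------------------------------------------
# Newick I/O (dendropy does the parsing; we keep our own array container)
# ---------------------------------------------------------------------------

def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are required on every edge except the root edge (which is
    ignored if present).  Internal node labels are optional and preserved.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"could not parse Newick: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(dnodes)}
    parent = np.full(len(dnodes), -1, dtype=int)
    blen = np.zeros(len(dnodes))
    labels: list = [None] * len(dnodes)
    for nd in dnodes:
        k = index[id(nd)]
        if nd.parent_node is not None:
            parent[k] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickError(
                    f"missing branch length on edge above node {k} "
                    f"(label {nd.taxon.label if nd.taxon else nd.label!r})"
                )
            blen[k] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[k] = nd.taxon.label
        elif nd.label:
            labels[k] = nd.label
    tip_labels = [labels[k] for k, nd in enumerate(dnodes) if nd.is_leaf()]
    if len(set(tip_labels)) != len(tip_labels):
        dup = sorted({x for x in tip_labels if tip_labels.count(x) > 1})
        raise NewickError(f"duplicate tip labels: {dup}")
    return Phylogeny(parent, blen, labels, root=0)


def write_newick(tree: Phylogeny) -> str:
    """Serialize a :class:`Phylogeny` to Newick (12 significant digits)."""
    ch = tree.children

    def render(v: int) -> str:
        if ch[v]:
            inner = ",".join(render(c) for c in ch[v])
            lab = tree.labels[v] or ""
            s = f"({inner}){lab}"
        else:
            s = tree.labels[v]
        if tree.parent[v] >= 0:
            s += f":{tree.blen[v]:.12g}"
        return s

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def _grow_birth_death(n_tips: int, lam: float, mu: float, rng) -> "Phylogeny | None":
    """One forward Gillespie realization, cut at the event after the n-th birth.

    The crown starts with two lineages at time 0.  Waiting times between
    events are exponential with rate k*(lam+mu) for k extant lineages; each
    event hits a uniformly chosen lineage and is a speciation with
    probability lam/(lam+mu), an extinction otherwise.  The first time the
    extant count reaches `n_tips` we draw one more waiting time and cut the
    tree there, so terminal branches have positive length.  Returns ``None``
    if the clade dies before reaching `n_tips` (caller retries).
    """
    parent = [-1, 0, 0]
    btime = [0.0, 0.0, 0.0]  # birth time of the node's branch start
    end_time = [0.0, None, None]  # None = extant
    active = [1, 2]
    t = 0.0
    total_rate = lam + mu
    # cap on event count guards pathological parameter choices
    for _ in range(200 * n_tips + 10_000):
        k = len(active)
        wait = rng.exponential(1.0 / (k * total_rate))
        if k == n_tips:
            t_cut = t + wait
            for v in active:
                end_time[v] = t_cut
            return _assemble(parent, btime, end_time, active)
        t += wait
        idx = int(rng.integers(k))
        v = active[idx]
        if rng.random() < lam / total_rate:  # speciation
            end_time[v] = t
            for _ in range(2):
                parent.append(v)
                btime.append(t)
                end_time.append(None)
            active[idx] = len(parent) - 2
            active.append(len(parent) - 1)
        else:  # extinction
            end_time[v] = t
            active.pop(idx)
            if not active:
                return None
    return None


def _assemble(parent, btime, end_time, extant) -> Phylogeny:
    """Prune extinct lineages, suppress unifurcations, root at the extant MRCA."""
    n = len(parent)
    keep = [False] * n
    for v in extant:
        while v != -1 and not keep[v]:
            keep[v] = True
            v = parent[v]
    # splice out kept nodes with exactly one kept child
    kept_children = [[] for _ in range(n)]
    for v in range(n):
        if keep[v] and parent[v] != -1:
            kept_children[parent[v]].append(v)
    extant_set = set(extant)

    # find new root: walk down from old root while there is a single kept child
    root = 0
    while len(kept_children[root]) == 1 and root not in extant_set:
        root = kept_children[root][0]

    # iterative preorder rebuild, splicing out unifurcating chains
    new_parent: list = []
    new_blen: list = []
    new_labels: list = []
    stack = [(root, -1, None)]  # None start => zero-length root edge
    while stack:
        v, par_new, start = stack.pop()
        while v not in extant_set and len(kept_children[v]) == 1:
            v = kept_children[v][0]
        k = len(new_parent)
        new_parent.append(par_new)
        new_blen.append(0.0 if start is None else end_time[v] - start)
        new_labels.append(None)
        for c in reversed(kept_children[v]):
            stack.append((c, k, end_time[v]))
    # deterministic tip labels in preorder (nodes were emitted in preorder)
    has_child = [False] * len(new_parent)
    for p in new_parent:
        if p >= 0:
            has_child[p] = True
    k = 0
    for v in range(len(new_parent)):
        if not has_child[v]:
            k += 1
            new_labels[v] = f"t{k}"
    return Phylogeny(np.array(new_parent), np.array(new_blen), new_labels, root=0)


def _root_split_ok(tree: Phylogeny, min_side: int) -> bool:
    ch = tree.children[tree.root]
    if len(ch) != 2:
        return False
    counts = []
    for c in ch:
        stack, cnt = [c], 0
        while stack:
            v = stack.pop()
            if not tree.children[v]:
                cnt += 1
            stack.extend(tree.children[v])
        counts.append(cnt)
    return min(counts) >= min_side


def simulate_birth_death(
    n_tips: int,
    net_diversification: float,
    turnover: float = 0.0,
    seed: int | None = None,
    min_tips_per_root_side: int = 0,
    height: "float | None" = 1.0,
) -> Phylogeny:
    """Simulate a reconstructed birth-death tree with `n_tips` extant tips.

    The speciation and extinction rates are recovered from
    ``lam = net_diversification / (1 - turnover)`` and ``mu = lam * turnover``.
    Extinct lineages are pruned, the tree is rooted at the MRCA of the extant
    tips, and (by default) rescaled to height 1.  Trees failing the root-split
    condition (each root child subtending at least `min_tips_per_root_side`
    tips) are rejected and redrawn; so are full-clade extinctions.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    if not (0 <= turnover < 1):
        raise ValueError("turnover must be in [0, 1)")
    if net_diversification <= 0:
        raise ValueError("net_diversification must be positive")
    if min_tips_per_root_side > n_tips // 2:
        raise ValueError("min_tips_per_root_side cannot exceed floor(n_tips/2)")
    lam = net_diversification / (1.0 - turnover)
    mu = lam * turnover
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_REJECTIONS):
        tree = _grow_birth_death(n_tips, lam, mu, rng)
        if tree is None:
            continue
        if not _root_split_ok(tree, min_tips_per_root_side):
            continue
        return tree if height is None else tree.rescaled(height)
    raise SimulationError(
        f"rejection budget ({_MAX_REJECTIONS}) exhausted; constraint: "
        f"{n_tips} extant tips with >= {min_tips_per_root_side} per root side"
    )


def simulate_yule(
    n_tips: int,
    birth_rate: float,
    seed: int | None = None,
    min_tips_per_root_side: int = 0,
    height: "float | None" = 1.0,
) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree; see :func:`simulate_birth_death`.

    This is the birth-death simulator at turnover 0, sharing its random
    stream, so the same seed yields the same tree for both entry points.
    """
    return simulate_birth_death(
        n_tips, birth_rate, turnover=0.0, seed=seed,
        min_tips_per_root_side=min_tips_per_root_side, height=height,
    )
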