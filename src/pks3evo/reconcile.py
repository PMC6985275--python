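"""Maximum-parsimony gene-tree / species-tree reconciliation.

Events and costs
----------------
A reconciliation maps every gene-tree node ``u`` to a species-tree node
``m(u)`` (gene leaves map to the species carrying them) and labels every
internal gene node with one event:

* **co-divergence** (speciation) at an internal species node ``x``: one
  child image lies in each of ``x``'s child subtrees (cost 0 by default);
* **duplication** on the edge above ``x``: both child images lie in the
  subtree of ``x`` (default cost 1.5);
* **transfer** from the edge above ``x``: one child image stays in the
  subtree of ``x``, the other lands on a species node *incomparable* to
  ``x`` — never an ancestor or descendant (default cost 6).

Losses (default cost 1) are charged per species-tree edge a child image
sits below its expected starting point.  The model is undated: transfers
are only constrained to incomparable nodes during the dynamic program, and
a temporal-feasibility check (cycle detection on the ordering constraints
the transfers impose on species-node times) runs afterwards on the
co-optimal solutions — so a reconciliation can *fail* feasibility, which
is reported rather than silently repaired.

The minimum cost, the exact number of co-optimal solutions (exact integer
arithmetic; costs are scaled to integers so 1.5 never meets float ties),
and one canonical optimal solution (fewest transfers, then fewest
duplications, then earliest postorder placement, restricted to temporally
feasible solutions when any exists) are all computed.

Multifurcating gene trees (weak edges collapsed upstream) are resolved to
the minimum-cost binary resolution: exhaustively up to a configurable
resolution budget, greedily (deepest species-LCA agglomeration) beyond it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from math import lcm
from typing import Iterable, Mapping

import pandas as pd

from .trees import TreeNode

__all__ = [
    "CostScheme",
    "ReconciliationResult",
    "reconcile_dtl",
    "reconcile_dl",
    "lca_reconcile",
    "summarize_events",
    "format_event_table",
]

_INF = 1 << 60


@dataclass(frozen=True)
class CostScheme:
    """Event costs; the defaults follow a published metabolic-enzyme
    analysis: duplication 1.5, loss 1, transfer 6, co-divergence 0."""

    duplication: float = 1.5
    loss: float = 1.0
    transfer: float = 6.0
    codivergence: float = 0.0

    def __post_init__(self):
        for name in ("duplication", "loss", "transfer", "codivergence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cost must be >= 0")

    def as_integers(self) -> tuple[int, int, int, int, int]:
        """(codiv, dup, transfer, loss, scale): costs scaled to integers."""
        fracs = [
            Fraction(str(getattr(self, n)))
            for n in ("codivergence", "duplication", "transfer", "loss")
        ]
        scale = lcm(*(f.denominator for f in fracs))
        dc, du, tc, lc = (int(f * scale) for f in fracs)
        return dc, du, tc, lc, scale


@dataclass
class ReconciliationResult:
    """Outcome of one reconciliation.

    ``codivergences``/``duplications``/``transfers``/``losses`` describe
    one canonical optimal solution; they are ``None`` when every
    co-optimal solution is temporally infeasible.  ``n_optimal`` counts
    all co-optimal solutions (feasible or not).  When the co-optimal count
    exceeds the enumeration cap, ``feasibility_exhaustive`` is False and
    the canonical solution is the best within the enumerated prefix.
    """

    model: str
    cost: float
    codivergences: int | None
    duplications: int | None
    transfers: int | None
    losses: int | None
    n_optimal: int
    feasible: bool
    feasibility_exhaustive: bool = True
    events: list[tuple[str, str, str]] | None = None


# ---------------------------------------------------------------------------
# species / gene tree indexing
# ---------------------------------------------------------------------------

class _SpeciesIndex:
    def __init__(self, tree: TreeNode):
        self.post = list(tree.postorder())
        self.n = len(self.post)
        self.idx = {id(node): i for i, node in enumerate(self.post)}
        self.label = [node.label for node in self.post]
        self.children = [
            [self.idx[id(c)] for c in node.children] for node in self.post
        ]
        for ch in self.children:
            if len(ch) not in (0, 2):
                raise ValueError("species tree must be binary")
        self.parent = [
            self.idx[id(node.parent)] if node.parent is not None else -1
            for node in self.post
        ]
        self.root = self.n - 1
        self.lo = [0] * self.n
        self.depth = [0] * self.n
        for i, node in enumerate(self.post):
            self.lo[i] = i if not self.children[i] else min(
                self.lo[c] for c in self.children[i]
            )
        # depth via preorder (parents have higher postorder index)
        for i in reversed(range(self.n)):
            p = self.parent[i]
            self.depth[i] = 0 if p == -1 else self.depth[p] + 1
        self.leaf_of = {
            self.label[i]: i for i in range(self.n) if not self.children[i]
        }

    def in_subtree(self, x: int, y: int) -> bool:
        """True when y lies in the subtree rooted at x (y == x included)."""
        return self.lo[x] <= y <= x

    def incomparable(self, x: int, y: int) -> bool:
        return not self.in_subtree(x, y) and not self.in_subtree(y, x)


def _check_binary(gene_tree: TreeNode) -> bool:
    for node in gene_tree.postorder():
        if node.children and len(node.children) != 2:
            return False
    return True


def _default_mapping(gene_tree: TreeNode, sp: _SpeciesIndex) -> dict[str, str]:
    mapping = {}
    for lab in gene_tree.leaf_labels():
        if lab in sp.leaf_of:
            mapping[lab] = lab
        elif "_" in lab and lab.rsplit("_", 1)[0] in sp.leaf_of:
            mapping[lab] = lab.rsplit("_", 1)[0]
        else:
            raise ValueError(f"gene leaf {lab!r} has no species mapping")
    return mapping


# ---------------------------------------------------------------------------
# the DP
# ---------------------------------------------------------------------------

class _DP:
    """Cost + solution-count dynamic program for one binary gene tree."""

    def __init__(self, gene_tree: TreeNode, sp: _SpeciesIndex,
                 sigma: Mapping[int, int], costs_int, allow_transfer: bool):
        self.sp = sp
        self.gpost = list(gene_tree.postorder())
        self.sigma = sigma
        self.dc, self.du, self.tc, self.lc = costs_int
        self.allow_transfer = allow_transfer
        self.c: dict[int, list[int]] = {}
        self.cn: dict[int, list[int]] = {}
        self.inn: dict[int, list[int]] = {}
        self.innN: dict[int, list[int]] = {}
        self.out: dict[int, list[int]] = {}
        self.outN: dict[int, list[int]] = {}
        self.root = self.gpost[-1]
        self._fill()

    def _fill(self):
        sp = self.sp
        S = sp.n
        for u in self.gpost:
            uid = id(u)
            if u.is_leaf:
                cu, nu = [_INF] * S, [0] * S
                x = self.sigma[uid]
                cu[x], nu[x] = 0, 1
            else:
                a, b = (id(ch) for ch in u.children)
                cu, nu = [_INF] * S, [0] * S
                ia, ina = self.inn[a], self.innN[a]
                ib, inb = self.inn[b], self.innN[b]
                oa, ona = self.out[a], self.outN[a]
                ob, onb = self.out[b], self.outN[b]
                for x in range(S):
                    options = []
                    ch = sp.children[x]
                    if ch:
                        x1, x2 = ch
                        if ia[x1] < _INF and ib[x2] < _INF:
                            options.append(
                                (self.dc + ia[x1] + ib[x2], ina[x1] * inb[x2])
                            )
                        if ia[x2] < _INF and ib[x1] < _INF:
                            options.append(
                                (self.dc + ia[x2] + ib[x1], ina[x2] * inb[x1])
                            )
                    if ia[x] < _INF and ib[x] < _INF:
                        options.append((self.du + ia[x] + ib[x], ina[x] * inb[x]))
                    if self.allow_transfer:
                        if ia[x] < _INF and ob[x] < _INF:
                            options.append(
                                (self.tc + ia[x] + ob[x], ina[x] * onb[x])
                            )
                        if ib[x] < _INF and oa[x] < _INF:
                            options.append(
                                (self.tc + ib[x] + oa[x], inb[x] * ona[x])
                            )
                    if options:
                        m = min(v for v, _ in options)
                        if m < _INF:
                            cu[x] = m
                            nu[x] = sum(k for v, k in options if v == m)
            self.c[uid], self.cn[uid] = cu, nu
            self._fill_in_out(uid, cu, nu)

    def _fill_in_out(self, uid, cu, nu):
        sp, S, lc = self.sp, self.sp.n, self.lc
        inn, innN = [_INF] * S, [0] * S
        for x in range(S):  # postorder: children first
            v, k = cu[x], nu[x]
            for w in sp.children[x]:
                if inn[w] < _INF and inn[w] + lc < v:
                    v, k = inn[w] + lc, 0
            if v < _INF:
                k = (nu[x] if cu[x] == v else 0) + sum(
                    innN[w] for w in sp.children[x]
                    if inn[w] < _INF and inn[w] + lc == v
                )
            inn[x], innN[x] = v, k
        # best over subtree (no loss weighting) for transfer targets
        best, bestN = [_INF] * S, [0] * S
        for x in range(S):
            v = cu[x]
            for w in sp.children[x]:
                v = min(v, best[w])
            if v < _INF:
                k = (nu[x] if cu[x] == v else 0) + sum(
                    bestN[w] for w in sp.children[x] if best[w] == v
                )
            else:
                k = 0
            best[x], bestN[x] = v, k
        out, outN = [_INF] * S, [0] * S
        for x in reversed(range(S)):  # preorder: parents first
            p = self.sp.parent[x]
            if p == -1:
                continue
            cands = [(out[p], outN[p])]
            for sib in sp.children[p]:
                if sib != x:
                    cands.append((best[sib], bestN[sib]))
            v = min(c for c, _ in cands)
            out[x] = v
            outN[x] = sum(k for c, k in cands if c == v) if v < _INF else 0
        self.inn[uid], self.innN[uid] = inn, innN
        self.out[uid], self.outN[uid] = out, outN

    # -- results -----------------------------------------------------------
    def min_cost(self) -> int:
        return min(self.c[id(self.root)])

    def n_optimal(self) -> int:
        croot, nroot = self.c[id(self.root)], self.cn[id(self.root)]
        m = min(croot)
        return sum(k for v, k in zip(croot, nroot) if v == m)

    # -- enumeration of co-optimal solutions -------------------------------
    def solutions(self):
        """Yield co-optimal solutions as {gene-node-id: (species, event)}."""
        croot = self.c[id(self.root)]
        m = min(croot)
        if m >= _INF:
            return
        for x in range(self.sp.n):
            if croot[x] == m:
                yield from self._enum_c(self.root, x)

    def _enum_c(self, u: TreeNode, x: int):
        uid = id(u)
        if u.is_leaf:
            yield {uid: (x, "leaf")}
            return
        target = self.c[uid][x]
        a, b = u.children
        ia, ib = self.inn[id(a)], self.inn[id(b)]
        ch = self.sp.children[x]
        if ch:
            x1, x2 = ch
            for xa, xb in ((x1, x2), (x2, x1)):
                if ia[xa] < _INF and ib[xb] < _INF and \
                        self.dc + ia[xa] + ib[xb] == target:
                    yield from self._pair(uid, x, "codiv", a, xa, b, xb)
        if ia[x] < _INF and ib[x] < _INF and \
                self.du + ia[x] + ib[x] == target:
            yield from self._pair(uid, x, "duplication", a, x, b, x)
        if self.allow_transfer:
            for stay, move in ((a, b), (b, a)):
                si, mo = self.inn[id(stay)], self.out[id(move)]
                if si[x] < _INF and mo[x] < _INF and \
                        self.tc + si[x] + mo[x] == target:
                    for s1 in self._enum_in(stay, x):
                        for s2 in self._enum_out(move, x):
                            yield {**s1, **s2, uid: (x, "transfer")}

    def _pair(self, uid, x, event, a, xa, b, xb):
        for s1 in self._enum_in(a, xa):
            for s2 in self._enum_in(b, xb):
                yield {**s1, **s2, uid: (x, event)}

    def _enum_in(self, u: TreeNode, x: int):
        target = self.inn[id(u)][x]
        if self.c[id(u)][x] == target:
            yield from self._enum_c(u, x)
        for w in self.sp.children[x]:
            if self.inn[id(u)][w] < _INF and self.inn[id(u)][w] + self.lc == target:
                yield from self._enum_in(u, w)

    def _enum_out(self, u: TreeNode, x: int):
        target = self.out[id(u)][x]
        cu = self.c[id(u)]
        for y in range(self.sp.n):
            if cu[y] == target and self.sp.incomparable(x, y):
                yield from self._enum_c(u, y)


def _solution_counts(sol, gpost, sp: _SpeciesIndex):
    codiv = dup = trans = loss = 0
    for u in gpost:
        if u.is_leaf:
            continue
        x, event = sol[id(u)]
        za = sol[id(u.children[0])][0]
        zb = sol[id(u.children[1])][0]
        if event == "codiv":
            codiv += 1
            loss += (sp.depth[za] - sp.depth[x] - 1) + (
                sp.depth[zb] - sp.depth[x] - 1
            )
        elif event == "duplication":
            dup += 1
            loss += (sp.depth[za] - sp.depth[x]) + (sp.depth[zb] - sp.depth[x])
        else:  # transfer
            trans += 1
            stay = za if sp.in_subtree(x, za) else zb
            loss += sp.depth[stay] - sp.depth[x]
    return codiv, dup, trans, loss


def _solution_transfers(sol, gpost, sp: _SpeciesIndex):
    transfers = []
    for u in gpost:
        if u.is_leaf:
            continue
        x, event = sol[id(u)]
        if event != "transfer":
            continue
        za = sol[id(u.children[0])][0]
        zb = sol[id(u.children[1])][0]
        recipient = zb if sp.in_subtree(x, za) else za
        transfers.append((x, recipient))
    return transfers


def _is_feasible(transfers, sp: _SpeciesIndex) -> bool:
    """Cycle check on the species-node time-ordering constraint graph.

    Donor edge (p(x), x) and recipient edge (p(z), z) must overlap in
    time: p(x) before z and p(z) before x.  Ancestor-descendant order is
    added for internal nodes; constraints ending at leaves always hold
    (leaves are the youngest points of an ultrametric tree) and are
    dropped.
    """
    if not transfers:
        return True
    edges: set[tuple[int, int]] = set()
    internal = [i for i in range(sp.n) if sp.children[i]]
    for i in internal:
        p = sp.parent[i]
        if p != -1:
            edges.add((p, i))
    for x, z in transfers:
        px, pz = sp.parent[x], sp.parent[z]
        if px != -1 and sp.children[z]:
            edges.add((px, z))
        if pz != -1 and sp.children[x]:
            edges.add((pz, x))
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {i: WHITE for i in range(sp.n)}
    for start in range(sp.n):
        if color[start] != WHITE:
            continue
        stack = [(start, iter(adj.get(start, ())))]
        color[start] = GRAY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GRAY:
                    return False
                if color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, iter(adj.get(nxt, ()))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return True


# ---------------------------------------------------------------------------
# polytomy resolution
# ---------------------------------------------------------------------------

def _n_shapes(k: int) -> int:
    out = 1
    for i in range(2, k):
        out *= 2 * i - 1
    return out


def _binary_shapes(k: int):
    """All rooted binary shapes over items 0..k-1 as nested pairs."""
    shapes = [0]
    for item in range(1, k):
        shapes = [s for old in shapes for s in _insertions(old, item)]
    return shapes


def _insertions(shape, item):
    yield (shape, item)
    if isinstance(shape, tuple):
        for r in _insertions(shape[0], item):
            yield (r, shape[1])
        for r in _insertions(shape[1], item):
            yield (shape[0], r)


def _greedy_shape(leafsets: list[frozenset[int]], sp: _SpeciesIndex):
    """Agglomerate children by deepest species LCA (most related first)."""

    def lca_depth(s: frozenset[int]) -> int:
        # LCA of a set of species node indices = shallowest node whose
        # subtree contains them all; walk up from an arbitrary member
        x = min(s)
        while not all(sp.in_subtree(x, y) for y in s):
            x = sp.parent[x]
        return sp.depth[x]

    items = [(i, leafsets[i]) for i in range(len(leafsets))]
    while len(items) > 1:
        best = None
        for i, j in itertools.combinations(range(len(items)), 2):
            d = lca_depth(items[i][1] | items[j][1])
            if best is None or d > best[0]:
                best = (d, i, j)
        _, i, j = best
        merged = ((items[i][0], items[j][0]), items[i][1] | items[j][1])
        items = [it for k, it in enumerate(items) if k not in (i, j)]
        items.append(merged)
    return items[0][0]


def _apply_shape(node: TreeNode, shape) -> None:
    children = node.children
    for ch in children:
        ch.parent = None
    node.children = []

    def build(s) -> TreeNode:
        if isinstance(s, tuple):
            return TreeNode(children=[build(s[0]), build(s[1])])
        return children[s]

    if isinstance(shape, tuple):
        node.add_child(build(shape[0]))
        node.add_child(build(shape[1]))
    else:  # single child cannot happen for a polytomy
        node.add_child(build(shape))


def _build_resolution(gene_tree: TreeNode, poly_paths, combo) -> TreeNode:
    t = gene_tree.copy()
    tpre = list(t.preorder())
    for path_idx, shape in zip(poly_paths, combo):
        _apply_shape(tpre[path_idx], shape)
    return t


def _best_resolution(gene_tree: TreeNode, sp: _SpeciesIndex,
                     sigma_label: Mapping[str, str], costs_int,
                     allow_transfer: bool, resolution_cap: int):
    """Find a minimum-cost binary resolution and its DP.

    While the joint number of resolutions across all polytomies stays
    within ``resolution_cap`` the search is exhaustive (exact).  Beyond
    it, every polytomy starts from the greedy deepest-species-LCA shape
    and is then refined one polytomy at a time, exhaustively over its own
    shapes (up to degree 5), keeping any improvement.
    """

    def run(tree: TreeNode) -> "_DP":
        sigma = {
            id(leaf): sp.leaf_of[sigma_label[leaf.label]]
            for leaf in tree.leaves()
        }
        return _DP(tree, sp, sigma, costs_int, allow_transfer)

    pre = list(gene_tree.preorder())
    poly_paths = [i for i, n in enumerate(pre) if len(n.children) > 2]
    if not poly_paths:
        return run(gene_tree)

    total = 1
    for i in poly_paths:
        total *= _n_shapes(len(pre[i].children))

    if total <= resolution_cap:
        best_dp, best_cost = None, None
        all_choices = [_binary_shapes(len(pre[i].children)) for i in poly_paths]
        for combo in itertools.product(*all_choices):
            dp = run(_build_resolution(gene_tree, poly_paths, combo))
            cost = dp.min_cost()
            if best_cost is None or cost < best_cost:
                best_cost, best_dp = cost, dp
        return best_dp

    def leafset_of(node: TreeNode) -> frozenset:
        return frozenset(
            sp.leaf_of[sigma_label[lab]] for lab in node.leaf_labels()
        )

    combo = [
        _greedy_shape([leafset_of(c) for c in pre[i].children], sp)
        for i in poly_paths
    ]
    best_dp = run(_build_resolution(gene_tree, poly_paths, combo))
    best_cost = best_dp.min_cost()
    for j, i in enumerate(poly_paths):
        k = len(pre[i].children)
        if _n_shapes(k) > 105:  # degree > 5: keep the greedy shape
            continue
        for shape in _binary_shapes(k):
            if shape == combo[j]:
                continue
            trial = list(combo)
            trial[j] = shape
            dp = run(_build_resolution(gene_tree, poly_paths, trial))
            cost = dp.min_cost()
            if cost < best_cost:
                best_cost, best_dp, combo = cost, dp, trial
    return best_dp


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def reconcile_dtl(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    leaf_mapping: Mapping[str, str] | None = None,
    costs: CostScheme = CostScheme(),
    *,
    allow_transfer: bool = True,
    enum_cap: int = 20000,
    resolution_cap: int = 1000,
) -> ReconciliationResult:
    """Minimum-cost DTL reconciliation of a rooted gene tree.

    ``leaf_mapping`` maps gene-leaf labels to species-leaf labels; by
    default a leaf maps to the species of the same name, or to the prefix
    before the last underscore (the simulator's ``S3_2`` convention).
    """
    sp = _SpeciesIndex(species_tree)
    model = "DTL" if allow_transfer else "DL"
    if leaf_mapping is None:
        sigma_label = _default_mapping(gene_tree, sp)
    else:
        sigma_label = dict(leaf_mapping)
        for lab in gene_tree.leaf_labels():
            if lab not in sigma_label:
                raise ValueError(f"gene leaf {lab!r} has no species mapping")
    for lab, sl in sigma_label.items():
        if sl not in sp.leaf_of:
            raise ValueError(
                f"gene leaf {lab!r} maps to unknown species {sl!r}"
            )

    dc, du, tc, lc, scale = costs.as_integers()

    if gene_tree.is_leaf:
        return ReconciliationResult(
            model=model, cost=0.0, codivergences=0, duplications=0,
            transfers=0, losses=0, n_optimal=1, feasible=True,
            events=[],
        )

    dp = _best_resolution(
        gene_tree, sp, sigma_label, (dc, du, tc, lc), allow_transfer,
        resolution_cap,
    )
    best_cost = dp.min_cost()

    n_opt = dp.n_optimal()
    # canonical solution: scan co-optimal solutions (capped), prefer
    # temporally feasible ones, tie-break (transfers, duplications,
    # postorder placement vector)
    sols = list(itertools.islice(dp.solutions(), enum_cap))
    exhaustive = n_opt <= enum_cap

    def key(sol):
        _, d, t, _ = _solution_counts(sol, dp.gpost, sp)
        placement = tuple(sol[id(u)][0] for u in dp.gpost)
        return (t, d, placement)

    sols.sort(key=key)
    canonical = None
    for sol in sols:
        if _is_feasible(_solution_transfers(sol, dp.gpost, sp), sp):
            canonical = sol
            break
    feasible = canonical is not None

    cost_value = best_cost / scale
    if not feasible:
        return ReconciliationResult(
            model=model, cost=cost_value, codivergences=None,
            duplications=None, transfers=None, losses=None,
            n_optimal=n_opt, feasible=False,
            feasibility_exhaustive=exhaustive,
        )
    codiv, dup, trans, loss = _solution_counts(canonical, dp.gpost, sp)
    events = [
        (
            (u.label or f"node{i}"),
            canonical[id(u)][1],
            sp.label[canonical[id(u)][0]],
        )
        for i, u in enumerate(dp.gpost)
        if not u.is_leaf
    ]
    return ReconciliationResult(
        model=model, cost=cost_value, codivergences=codiv,
        duplications=dup, transfers=trans, losses=loss,
        n_optimal=n_opt, feasible=True,
        feasibility_exhaustive=exhaustive, events=events,
    )


def reconcile_dl(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    leaf_mapping: Mapping[str, str] | None = None,
    costs: CostScheme = CostScheme(),
    **kwargs,
) -> ReconciliationResult:
    """Duplication-loss reconciliation (transfers forbidden).

    For binary gene trees this reproduces the LCA reconciliation, which is
    the unique optimum whenever duplication and loss costs are positive.
    """
    return reconcile_dtl(
        gene_tree, species_tree, leaf_mapping, costs,
        allow_transfer=False, **kwargs,
    )


def lca_reconcile(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    leaf_mapping: Mapping[str, str] | None = None,
) -> tuple[int, int]:
    """Independent LCA-mapping recount of DL duplications and losses.

    Requires a binary gene tree.  Used as a cross-check of the dynamic
    program, not by it.
    """
    sp = _SpeciesIndex(species_tree)
    if not _check_binary(gene_tree):
        raise ValueError("lca_reconcile requires a binary gene tree")
    sigma_label = (
        _default_mapping(gene_tree, sp) if leaf_mapping is None
        else dict(leaf_mapping)
    )

    def lca(x: int, y: int) -> int:
        while not sp.in_subtree(x, y):
            x = sp.parent[x]
        return x

    m: dict[int, int] = {}
    dups = losses = 0
    for u in gene_tree.postorder():
        if u.is_leaf:
            m[id(u)] = sp.leaf_of[sigma_label[u.label]]
            continue
        a, b = u.children
        x = lca(m[id(a)], m[id(b)])
        m[id(u)] = x
        is_dup = m[id(a)] == x or m[id(b)] == x
        if is_dup:
            dups += 1
        for chi in (a, b):
            d = sp.depth[m[id(chi)]] - sp.depth[x]
            losses += d if is_dup else d - 1
    return dups, losses


# ---------------------------------------------------------------------------
# event-table aggregation
# ---------------------------------------------------------------------------

def summarize_events(rows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-family reconciliation rows into a per-clade table.

    ``rows`` needs columns: clade, model (``DTL``/``DL``), duplications,
    transfers, losses, n_optimal, feasible.  Event counts are summed per
    clade and model; a clade's DTL side is marked infeasible when it has
    DTL rows and none is feasible (counts then stay absent).  The
    co-optimal count is a per-family quantity and is only carried to the
    clade row when the clade has a single family; it is never multiplied
    across families.  A ``total`` row sums the per-clade values, the DTL
    side over feasible clades only.
    """
    required = {"clade", "model", "duplications", "transfers", "losses",
                "n_optimal", "feasible"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    out_rows = []
    for clade, sub in rows.groupby("clade", sort=True):
        rec: dict = {"clade": str(clade)}
        for model in ("DTL", "DL"):
            msub = sub[sub["model"] == model]
            prefix = model.lower()
            if msub.empty:
                rec[f"{prefix}_feasible"] = None
                for col in ("duplications", "transfers", "losses"):
                    rec[f"{prefix}_{col}"] = None
                rec[f"{prefix}_n_optimal"] = None
                continue
            feas = msub[msub["feasible"].astype(bool)]
            rec[f"{prefix}_feasible"] = not feas.empty
            if feas.empty:
                for col in ("duplications", "transfers", "losses"):
                    rec[f"{prefix}_{col}"] = None
                rec[f"{prefix}_n_optimal"] = None
            else:
                for col in ("duplications", "transfers", "losses"):
                    rec[f"{prefix}_{col}"] = int(feas[col].sum())
                rec[f"{prefix}_n_optimal"] = (
                    int(feas["n_optimal"].iloc[0]) if len(msub) == 1 else None
                )
        out_rows.append(rec)

    total: dict = {"clade": "total"}
    for prefix in ("dtl", "dl"):
        feas_rows = [
            r for r in out_rows if r.get(f"{prefix}_feasible") is True
        ]
        for col in ("duplications", "transfers", "losses"):
            total[f"{prefix}_{col}"] = (
                sum(r[f"{prefix}_{col}"] for r in feas_rows)
                if feas_rows else None
            )
        total[f"{prefix}_feasible"] = None
        total[f"{prefix}_n_optimal"] = None
    out_rows.append(total)
    # object dtype keeps exact ints next to None (no float64 coercion)
    return pd.DataFrame(out_rows, dtype=object)


def format_event_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Render a clade summary with DL values parenthesized next to DTL,
    infeasible DTL entries as dashes: ``"15 (15)"``, ``"-(34)"``."""

    def norm(v):
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return None
        return int(v)

    def cell(dtl, dl):
        dtl, dl = norm(dtl), norm(dl)
        left = "-" if dtl is None else f"{dtl:,}"
        if dl is None:
            return left
        return f"{left} ({dl:,})" if dtl is not None else f"-({dl:,})"

    rows = []
    for _, r in summary.iterrows():
        rows.append(
            {
                "clade": r["clade"],
                "duplications": cell(r["dtl_duplications"], r["dl_duplications"]),
                "transfers": cell(r["dtl_transfers"], r["dl_transfers"]),
                "losses": cell(r["dtl_losses"], r["dl_losses"]),
                "n_optimal": cell(r["dtl_n_optimal"], r["dl_n_optimal"]),
            }
        )
    return pd.DataFrame(rows)
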