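"""Distance and parsimony phylogenetics.

Implements the estimation toolkit used on curated single-copy gene
alignments: Jukes-Cantor distances and neighbor-joining for duplication
screening, and equal-weights maximum parsimony (Fitch scoring, heuristic
search with random-addition replicates, TBR branch swapping and an
optional parsimony ratchet) with strict consensus, nonparametric
bootstrap and the homoplasy indices CI and RI.

Character conventions follow "gaps treated as missing data": IUPAC
ambiguity codes are uncertainty state sets, and ``-`` / ``?`` are the
full state set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .records import Alignment, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "ParsimonyScore",
    "SearchSettings",
    "jc_distance",
    "neighbor_joining",
    "fitch_length",
    "fitch_site_steps",
    "site_step_bounds",
    "ci_ri",
    "parsimony_score",
    "mp_heuristic_search",
    "strict_consensus",
    "bootstrap_mp",
    "tree_splits",
    "rf_distance",
]

# 4-bit state-set encoding: A=1 C=2 G=4 T=8; ambiguity = union; gap/? = full set.
_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7,
    "N": 15, "-": 15, "?": 15, "X": 15,
}
_LUT = np.zeros(128, dtype=np.uint8)
for ch, bits in _BITS.items():
    _LUT[ord(ch)] = bits
    _LUT[ord(ch.lower())] = bits

_SINGLE = (1, 2, 4, 8)


def encode_alignment(alignment: Alignment, order: list[str] | None = None) -> np.ndarray:
    """Encode sequences (rows ordered by ``order``) as 4-bit state sets."""
    ids = order or alignment.ids()
    rows = []
    for sid in ids:
        rec = alignment[sid]
        arr = np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8)
        rows.append(_LUT[arr])
    enc = np.vstack(rows)
    if (enc == 0).any():
        raise ValidationError("alignment contains non-IUPAC characters")
    return enc


# ---------------------------------------------------------------------------
# Jukes-Cantor distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def jc_distance(alignment: Alignment) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances, d = -(3/4) ln(1 - (4/3) p).

    p is the mismatch proportion over sites where both sequences carry a
    single unambiguous base.  A pair differing at >= 75% of comparable
    sites has no finite JC distance and raises an error naming the pair.
    """
    if len(alignment) < 2:
        raise ValidationError("need at least two sequences")
    enc = encode_alignment(alignment)
    unamb = np.isin(enc, _SINGLE)
    ids = alignment.ids()
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = unamb[i] & unamb[j]
            m = int(both.sum())
            if m == 0:
                raise ValidationError(
                    f"({ids[i]}, {ids[j]}): no comparable unambiguous sites"
                )
            p = float((enc[i][both] != enc[j][both]).sum()) / m
            if p >= 0.75:
                raise ValidationError(
                    f"({ids[i]}, {ids[j]}): p = {p:.3f} >= 0.75, "
                    "Jukes-Cantor distance undefined"
                )
            d[i, j] = d[j, i] = -0.75 * math.log1p(-(4.0 / 3.0) * p)
    return DistanceMatrix(taxa=list(ids), d=d)


# ---------------------------------------------------------------------------
# Neighbor-joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical NJ (Q criterion, Studier-Keppler update).

    Ties in Q are broken by the smallest (row, column) index pair in the
    current node ordering (original taxa first, agglomerated nodes
    appended).  Negative branch lengths are clamped to zero with a log
    note.  Returns an unrooted dendropy tree (trifurcating seed node).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValidationError("neighbor-joining requires >= 3 taxa")

    ns = dendropy.TaxonNamespace(dm.taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for label in dm.taxa:
        nd = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(nd)

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            logger.info("NJ: negative branch length %.3g on %s--%s clamped to 0", x, a, b)
            return 0.0
        return x

    active = list(range(n))  # indices into `nodes`
    D = {(i, j): dm.d[i, j] for i in range(n) for j in range(n) if i != j}

    def dist(i, j):
        return D[(i, j)] if i != j else 0.0

    next_label = n
    while len(active) > 3:
        r = len(active)
        R = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist(i, j) - R[i] - R[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * dist(i, j) + (R[i] - R[j]) / (2 * (r - 2))
        lj = dist(i, j) - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(li, str(i), str(j))
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lj, str(j), str(i))
        u = next_label
        next_label += 1
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            D[(u, k)] = D[(k, u)] = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    root = dendropy.Node()
    la = 0.5 * (dist(i, j) + dist(i, k) - dist(j, k))
    lb = 0.5 * (dist(i, j) + dist(j, k) - dist(i, k))
    lc = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
    for idx, ln in ((i, la), (j, lb), (k, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(ln, str(idx), "center")
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Fitch scoring on dendropy trees


def fitch_site_steps(tree: dendropy.Tree, alignment: Alignment) -> np.ndarray:
    """Per-site Fitch step counts on an arbitrary rooting of ``tree``.

    Tip labels must match alignment sequence ids exactly.  Polytomies
    are folded child-by-child (exact for binary trees, an upper bound at
    polytomies).
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ids = set(alignment.ids())
    if tips != ids:
        diff = sorted(tips.symmetric_difference(ids))
        raise ValidationError(f"tip/sequence mismatch: {diff}")
    enc = encode_alignment(alignment)
    row = {sid: enc[i] for i, sid in enumerate(alignment.ids())}
    n_sites = enc.shape[1]
    steps = np.zeros(n_sites, dtype=np.int64)
    state: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state[id(node)] = row[node.taxon.label]
            continue
        children = node.child_nodes()
        acc = state.pop(id(children[0]))
        for ch in children[1:]:
            other = state.pop(id(ch))
            inter = acc & other
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | other, inter)
        state[id(node)] = acc
    return steps


def fitch_length(tree: dendropy.Tree, alignment: Alignment) -> int:
    """Total Fitch tree length (equal weights)."""
    return int(fitch_site_steps(tree, alignment).sum())


# ---------------------------------------------------------------------------
# Step bounds and homoplasy indices


def site_step_bounds(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (minimum, maximum) parsimony steps.

    Minimum = distinct unambiguous states - 1; maximum = unambiguous
    occurrences - frequency of the commonest state (the star-tree bound).
    """
    enc = encode_alignment(alignment)
    counts = np.stack([(enc == b).sum(axis=0) for b in _SINGLE])  # 4 x sites
    present = (counts > 0).sum(axis=0)
    m = np.maximum(present - 1, 0)
    total = counts.sum(axis=0)
    M = np.where(total > 0, total - counts.max(axis=0), 0)
    return m.astype(np.int64), M.astype(np.int64)


def _informative_mask(alignment: Alignment) -> np.ndarray:
    """Parsimony-informative sites: >= 2 states each in >= 2 sequences."""
    enc = encode_alignment(alignment)
    counts = np.stack([(enc == b).sum(axis=0) for b in _SINGLE])
    return (counts >= 2).sum(axis=0) >= 2


def ci_ri(L: int, m: int, M: int) -> tuple[float, float | None]:
    """Consistency index m/L and retention index (M-L)/(M-m).

    RI is undefined (None) when M == m.
    """
    if not (m <= L <= M):
        raise ValidationError(f"require m <= L <= M, got {m}, {L}, {M}")
    if L <= 0:
        raise ValidationError("CI undefined for L = 0")
    ci = m / L
    ri = None if M == m else (M - L) / (M - m)
    return ci, ri


@dataclass(frozen=True)
class ParsimonyScore:
    """Tree length with its per-site bounds and the derived indices."""

    L: int
    m: int
    M: int
    include_uninformative: bool = True

    @property
    def CI(self) -> float:
        return ci_ri(self.L, self.m, self.M)[0]

    @property
    def RI(self) -> float | None:
        return ci_ri(self.L, self.m, self.M)[1]

    def as_dict(self) -> dict:
        ci, ri = ci_ri(self.L, self.m, self.M)
        return {
            "L": self.L,
            "m": self.m,
            "M": self.M,
            "CI": round(ci, 3),
            "RI": None if ri is None else round(ri, 3),
            "include_uninformative": self.include_uninformative,
        }


def parsimony_score(
    tree: dendropy.Tree, alignment: Alignment, include_uninformative: bool = True
) -> ParsimonyScore:
    """Score a tree: L, the step bounds, CI and RI.

    ``include_uninformative=False`` restricts all three sums to
    parsimony-informative sites (the alternative convention PAUP* also
    reports).
    """
    steps = fitch_site_steps(tree, alignment)
    m, M = site_step_bounds(alignment)
    if not include_uninformative:
        keep = _informative_mask(alignment)
        steps, m, M = steps[keep], m[keep], M[keep]
    return ParsimonyScore(
        L=int(steps.sum()), m=int(m.sum()), M=int(M.sum()),
        include_uninformative=include_uninformative,
    )


# ---------------------------------------------------------------------------
# Internal unrooted-tree representation for the MP search


class _Topo:
    """Unrooted binary tree over leaves 0..n-1 as an adjacency map."""

    __slots__ = ("adj", "n_leaves", "next_id")

    def __init__(self, adj: dict[int, list[int]], n_leaves: int, next_id: int):
        self.adj = adj
        self.n_leaves = n_leaves
        self.next_id = next_id

    @classmethod
    def star3(cls, n_leaves: int) -> "_Topo":
        c = n_leaves
        adj = {0: [c], 1: [c], 2: [c], c: [0, 1, 2]}
        return cls(adj, n_leaves, c + 1)

    def copy(self) -> "_Topo":
        return _Topo({k: list(v) for k, v in self.adj.items()}, self.n_leaves, self.next_id)

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u in sorted(self.adj):
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def attach(self, leaf: int, edge: tuple[int, int]) -> None:
        """Attach ``leaf`` by subdividing ``edge`` (in place)."""
        u, v = edge
        w = self.next_id
        self.next_id += 1
        self.adj[u].remove(v)
        self.adj[v].remove(u)
        self.adj[u].append(w)
        self.adj[v].append(w)
        self.adj[w] = [u, v, leaf]
        self.adj[leaf] = [w]

    # -- scoring -----------------------------------------------------------

    def fitch_steps(self, enc: np.ndarray, weights: np.ndarray | None = None) -> int:
        """Weighted Fitch length; leaf i reads row i of ``enc``."""
        root = 0
        start = self.adj[root][0]
        # iterative postorder from `start` with parent `root`
        order: list[tuple[int, int]] = []
        stack = [(start, root)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        state: dict[int, np.ndarray] = {}
        total = 0
        w = weights
        for node, parent in reversed(order):
            if node < self.n_leaves:
                state[node] = enc[node]
                continue
            children = [nb for nb in self.adj[node] if nb != parent]
            acc = state.pop(children[0])
            for ch in children[1:]:
                other = state.pop(ch)
                inter = acc & other
                empty = inter == 0
                total += int(empty.sum()) if w is None else int(w[empty].sum())
                acc = np.where(empty, acc | other, inter)
            state[node] = acc
        inter = enc[root] & state[start]
        empty = inter == 0
        total += int(empty.sum()) if w is None else int(w[empty].sum())
        return total

    # -- identity ----------------------------------------------------------

    def splits(self) -> frozenset:
        """Nontrivial splits as leaf bitmasks of the side without leaf 0."""
        masks: dict[tuple[int, int], int] = {}

        def side_mask(u: int, parent: int) -> int:
            mask = 0
            stack = [(u, parent)]
            while stack:
                node, par = stack.pop()
                if node < self.n_leaves:
                    mask |= 1 << node
                for nb in self.adj[node]:
                    if nb != par:
                        stack.append((nb, node))
            return mask

        out = set()
        full = (1 << self.n_leaves) - 1
        for u, v in self.edges():
            mask = side_mask(v, u)
            if mask & 1:
                mask = full ^ mask
            c = bin(mask).count("1")
            if 2 <= c <= self.n_leaves - 2:
                out.add(mask)
        return frozenset(out)

    # -- conversion --------------------------------------------------------

    def to_newick(self, labels: list[str]) -> str:
        root = 0
        start = self.adj[root][0]

        def sub(node: int, parent: int) -> str:
            if node < self.n_leaves:
                return labels[node]
            parts = [sub(nb, node) for nb in self.adj[node] if nb != parent]
            return "(" + ",".join(parts) + ")"

        inner = [sub(nb, start) for nb in self.adj[start] if nb != root]
        return f"({labels[root]},{','.join(inner)});"

    def to_dendropy(self, labels: list[str],
                    taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tree = dendropy.Tree.get(
            data=self.to_newick(labels),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )
        tree.is_rooted = False
        return tree


def _tbr_neighbors(topo: _Topo):
    """Yield the TBR neighborhood of an unrooted binary tree.

    Each edge is bisected; the two resulting subtrees (degree-2 stumps
    suppressed) are reconnected across every pair of their edges.  For a
    single-leaf component the leaf itself is the attachment point, which
    makes SPR moves a subset of the neighborhood.
    """
    for (u, v) in topo.edges():
        base = topo.copy()
        base.adj[u].remove(v)
        base.adj[v].remove(u)

        def component(start: int) -> list[int]:
            seen = {start}
            stack = [start]
            while stack:
                x = stack.pop()
                for nb in base.adj[x]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            return sorted(seen)

        def suppress(x: int) -> int:
            """Suppress a degree-2 stump; return an anchor on its side."""
            if x >= base.n_leaves and len(base.adj[x]) == 2:
                a, b = base.adj[x]
                base.adj[a].remove(x)
                base.adj[b].remove(x)
                base.adj[a].append(b)
                base.adj[b].append(a)
                del base.adj[x]
                return a
            return x

        anchor_u = suppress(u)
        anchor_v = suppress(v)
        side_u = component(anchor_u)
        side_v = component(anchor_v)

        def attach_points(side: list[int]):
            if len(side) == 1:
                return [side[0]]
            pts = []
            sset = set(side)
            for a in side:
                for b in base.adj[a]:
                    if b in sset and a < b:
                        pts.append((a, b))
            return pts

        for pa in attach_points(side_u):
            for pb in attach_points(side_v):
                t = base.copy()

                def endpoint(t: _Topo, p):
                    if isinstance(p, int):
                        return p
                    a, b = p
                    w = t.next_id
                    t.next_id += 1
                    t.adj[a].remove(b)
                    t.adj[b].remove(a)
                    t.adj[a].append(w)
                    t.adj[b].append(w)
                    t.adj[w] = [a, b]
                    return w

                ea = endpoint(t, pa)
                eb = endpoint(t, pb)
                t.adj[ea].append(eb)
                t.adj[eb].append(ea)
                yield t


@dataclass(frozen=True)
class SearchSettings:
    """Heuristic MP search parameters.

    ``n_random_additions`` random-addition-sequence replicates each run
    stepwise addition followed by TBR swapping; ``ratchet_iterations``
    rounds of the parsimony ratchet (25% of characters upweighted x2)
    may follow each replicate.  Gaps are always treated as missing and
    characters are equally weighted.
    """

    n_random_additions: int = 10
    ratchet_iterations: int = 0
    trees_saved_per_replicate: int = 10
    max_best_trees: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_random_additions < 1 or self.trees_saved_per_replicate < 1:
            raise ValidationError("search counts must be positive")
        if self.ratchet_iterations < 0:
            raise ValidationError("ratchet_iterations must be >= 0")


def _stepwise_addition(enc: np.ndarray, order: list[int]) -> _Topo:
    """Greedy stepwise addition following ``order`` (first three seed a star)."""
    n = enc.shape[0]
    relabel = {new: orig for new, orig in enumerate(order)}
    # build over the permuted leaf indexing, then map back via enc rows
    perm_enc = enc[order]
    topo = _Topo.star3(n)
    for leaf in range(3, n):
        best = None
        for edge in topo.edges():
            cand = topo.copy()
            cand.attach(leaf, edge)
            s = cand.fitch_steps(perm_enc)
            if best is None or s < best[0]:
                best = (s, cand)
        topo = best[1]
    # remap adjacency so leaf ids are the original alignment rows
    mapping = {}
    for node in topo.adj:
        mapping[node] = relabel[node] if node < n else node
    adj = {mapping[k]: [mapping[x] for x in v] for k, v in topo.adj.items()}
    return _Topo(adj, n, topo.next_id)


def _tbr_hill_climb(
    topo: _Topo,
    enc: np.ndarray,
    weights: np.ndarray | None,
    max_trees: int,
) -> tuple[list[_Topo], int]:
    """TBR to a local optimum, retaining up to ``max_trees`` tied trees."""
    best_score = topo.fitch_steps(enc, weights)
    best: dict[frozenset, _Topo] = {topo.splits(): topo}
    improved = True
    while improved:
        improved = False
        for t in list(best.values()):
            for nb in _tbr_neighbors(t):
                s = nb.fitch_steps(enc, weights)
                if s < best_score:
                    best_score = s
                    best = {nb.splits(): nb}
                    improved = True
                    break
                if s == best_score and len(best) < max_trees:
                    key = nb.splits()
                    if key not in best:
                        best[key] = nb
            if improved:
                break
    return list(best.values()), best_score


def _ratchet(
    topo: _Topo,
    enc: np.ndarray,
    rng: np.random.Generator,
    iterations: int,
    max_trees: int,
) -> tuple[list[_Topo], int]:
    """Parsimony ratchet: alternate searches under perturbed and original weights."""
    n_sites = enc.shape[1]
    best, best_score = _tbr_hill_climb(topo, enc, None, max_trees)
    current = best[0]
    for _ in range(iterations):
        weights = np.ones(n_sites, dtype=np.int64)
        k = max(1, int(round(0.25 * n_sites)))
        idx = rng.choice(n_sites, size=k, replace=False)
        weights[idx] = 2
        perturbed, _ = _tbr_hill_climb(current, enc, weights, 1)
        cand_set, cand_score = _tbr_hill_climb(perturbed[0], enc, None, max_trees)
        if cand_score < best_score:
            best, best_score = cand_set, cand_score
            current = cand_set[0]
        elif cand_score == best_score:
            existing = {t.splits(): t for t in best}
            for t in cand_set:
                if t.splits() not in existing and len(existing) < max_trees:
                    existing[t.splits()] = t
            best = list(existing.values())
            current = cand_set[0]
    return best, best_score


def mp_heuristic_search(
    alignment: Alignment, settings: SearchSettings | None = None
) -> tuple[list[dendropy.Tree], int]:
    """Heuristic maximum-parsimony search.

    Each random-addition replicate builds a starting tree by randomized
    stepwise addition, swaps it with TBR to a local optimum (keeping up
    to ``trees_saved_per_replicate`` tied trees) and optionally applies
    ratchet rounds.  The global best set is deduplicated by topology.
    Fully seed-reproducible.
    """
    settings = settings or SearchSettings()
    n = len(alignment)
    if n < 4:
        raise ValidationError("MP search requires >= 4 taxa")
    ids = alignment.ids()
    enc = encode_alignment(alignment)
    rng = np.random.default_rng(settings.seed)

    global_best: dict[frozenset, _Topo] = {}
    global_score: int | None = None
    for _ in range(settings.n_random_additions):
        order = [int(x) for x in rng.permutation(n)]
        start = _stepwise_addition(enc, order)
        if settings.ratchet_iterations > 0:
            trees, score = _ratchet(
                start, enc, rng, settings.ratchet_iterations,
                settings.trees_saved_per_replicate,
            )
        else:
            trees, score = _tbr_hill_climb(
                start, enc, None, settings.trees_saved_per_replicate
            )
        if global_score is None or score < global_score:
            global_score = score
            global_best = {t.splits(): t for t in trees}
        elif score == global_score:
            for t in trees:
                key = t.splits()
                if key not in global_best and len(global_best) < settings.max_best_trees:
                    global_best[key] = t

    ns = dendropy.TaxonNamespace(ids)
    out = [t.to_dendropy(ids, taxon_namespace=ns) for t in global_best.values()]
    return out, int(global_score)


# ---------------------------------------------------------------------------
# Splits, consensus, bootstrap


def tree_splits(tree: dendropy.Tree) -> frozenset:
    """Nontrivial splits as frozensets of tip labels (side excluding the
    lexicographically smallest label)."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = labels[0]
    full = set(labels)
    out = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = frozenset(full - side)
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return frozenset(out)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance (symmetric split difference)."""
    s1, s2 = tree_splits(t1), tree_splits(t2)
    return len(s1 ^ s2)


def strict_consensus(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Strict consensus: exactly the bipartitions common to all inputs."""
    if not trees:
        raise ValidationError("need at least one tree")
    tip_sets = [frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees]
    if len(set(tip_sets)) != 1:
        raise ValidationError("trees have differing tip sets")
    labels = sorted(tip_sets[0])
    common = set(tree_splits(trees[0]))
    for t in trees[1:]:
        common &= tree_splits(t)

    # Build rooted-at-ref tree: clades are the common split sides (which
    # exclude the reference label) plus the trivial singletons.
    ref = labels[0]
    others = [l for l in labels if l != ref]
    clades = sorted(common, key=len, reverse=True)
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    ref_leaf = dendropy.Node(taxon=ns.get_taxon(ref))
    root.add_child(ref_leaf)
    node_of: dict[frozenset, dendropy.Node] = {}

    def parent_clade(c: frozenset):
        best = None
        for other in clades:
            if c < other and (best is None or len(other) < len(best)):
                best = other
        return best

    for c in clades:
        node_of[c] = dendropy.Node()
    for c in clades:
        p = parent_clade(c)
        (node_of[p] if p is not None else root).add_child(node_of[c])
    for label in others:
        c = frozenset([label])
        p = parent_clade(c)
        leaf = dendropy.Node(taxon=ns.get_taxon(label))
        (node_of[p] if p is not None else root).add_child(leaf)
    tree.is_rooted = False
    return tree


def bootstrap_mp(
    alignment: Alignment,
    n_reps: int,
    settings: SearchSettings | None = None,
    seed: int = 0,
    reference_tree: dendropy.Tree | None = None,
) -> dendropy.Tree:
    """Nonparametric bootstrap with simple-addition MP searches.

    Each replicate resamples columns with replacement and runs a single
    simple-addition (input taxon order) + TBR search; the best trees'
    splits receive fractional credit when tied.  Supports (percent of
    replicates) are written as internal-node labels on the full-data MP
    tree (computed here if not supplied).
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    settings = settings or SearchSettings()
    ids = alignment.ids()
    enc = encode_alignment(alignment)
    n = len(ids)
    if n < 4:
        raise ValidationError("bootstrap requires >= 4 taxa")
    rng = np.random.default_rng(seed)

    if reference_tree is None:
        trees, _ = mp_heuristic_search(alignment, settings)
        reference_tree = trees[0]

    n_sites = enc.shape[1]
    credit: dict[int, float] = {}
    simple_order = list(range(n))
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        renc = enc[:, cols]
        start = _stepwise_addition(renc, simple_order)
        best, _ = _tbr_hill_climb(
            start, renc, None, settings.trees_saved_per_replicate
        )
        frac = 1.0 / len(best)
        rep_splits: dict[int, float] = {}
        for t in best:
            for s in t.splits():
                rep_splits[s] = rep_splits.get(s, 0.0) + frac
        for s, f in rep_splits.items():
            credit[s] = credit.get(s, 0.0) + min(f, 1.0)

    index = {label: i for i, label in enumerate(ids)}
    full = (1 << n) - 1
    annotated = reference_tree.clone(depth=1)
    for node in annotated.preorder_internal_node_iter():
        side = [l.taxon.label for l in node.leaf_iter()]
        if len(side) in (0, 1, n - 1, n):
            continue
        mask = 0
        for label in side:
            mask |= 1 << index[label]
        if mask & 1:
            mask = full ^ mask
        support = 100.0 * credit.get(mask, 0.0) / n_reps
        node.label = f"{support:.0f}"
    return annotated
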