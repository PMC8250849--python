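"""Event-based cophylogenetic reconciliation in a parsimony framework.

A symbiont tree is mapped onto a timed host tree under five event types —
cospeciation, duplication, duplication followed by host switching, loss
(sorting), and failure to diverge — each carrying a nonnegative cost.  A
reconciliation's total cost is the dot product of its event counts with the
cost scheme; the solver minimises this over all placements *and* over all
timings (total orders of the host's internal nodes consistent with ancestry).

Host switches are contemporaneous: a switching daughter may only jump to a
host edge alive in the same time slice.  Failure to diverge applies exactly
to symbiont tips linked to more than one host tip; such a tip is expanded
into a fan across its linked hosts, each spanned host speciation contributing
one failure-to-diverge event (and each one-sided crossing a loss).

For a fixed timing the optimal placement is found by dynamic programming over
(symbiont node, host edge, time slice); the exact solver enumerates every
timing of small trees, and the heuristic searches timing space with a seeded
evolutionary algorithm, solving each candidate timing exactly.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

__all__ = [
    "CostScheme",
    "EventCounts",
    "Tanglegram",
    "Reconciliation",
    "ReconciliationSummary",
    "SolverConfig",
    "RandomTreeTestResult",
    "cost_scheme_presets",
    "reconciliation_cost",
    "reconcile_exact",
    "reconcile_search",
    "random_tree_test",
    "random_binary_topology",
]

_INF = math.inf


@dataclass(frozen=True)
class CostScheme:
    """Per-event costs, in the order used throughout: cospeciation,
    duplication, duplication + host switch, loss, failure to diverge."""

    cospeciation: float
    duplication: float
    duplication_host_switch: float
    loss: float
    failure_to_diverge: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"negative cost for {name}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.cospeciation, self.duplication, self.duplication_host_switch,
                self.loss, self.failure_to_diverge)

    def as_dict(self) -> dict[str, float]:
        return {
            "cospeciation": self.cospeciation,
            "duplication": self.duplication,
            "duplication_host_switch": self.duplication_host_switch,
            "loss": self.loss,
            "failure_to_diverge": self.failure_to_diverge,
        }


@dataclass(frozen=True)
class EventCounts:
    n_cospeciation: int = 0
    n_duplication: int = 0
    n_switch: int = 0
    n_loss: int = 0
    n_ftd: int = 0

    def __post_init__(self) -> None:
        for v in self.as_tuple():
            if v < 0:
                raise ValueError("negative event count")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.n_cospeciation, self.n_duplication, self.n_switch,
                self.n_loss, self.n_ftd)


def reconciliation_cost(counts: EventCounts, scheme: CostScheme) -> float:
    """Total cost: sum of event counts weighted by the scheme's costs."""
    return float(sum(c * k for c, k in zip(counts.as_tuple(), scheme.as_tuple())))


def cost_scheme_presets() -> dict[str, CostScheme]:
    """The ten cost schemes used to probe sensitivity of the reconstruction.

    Vectors are (cospeciation, duplication, duplication+switch, loss, FTD).
    """
    raw = {
        "jane_default": (0, 1, 2, 1, 1),
        "treemap_default": (0, 1, 1, 1, 1),
        "treefitter_default": (0, 0, 2, 1, 1),
        "codivergence_adjusted": (1, 0, 1, 1, 1),
        "host_switch_adjusted": (0, 0, 1, 1, 1),
        "cospeciation_prohibited": (10, 1, 1, 1, 1),
        "host_switch_prohibited": (1, 1, 10, 1, 1),
        "sorting_prohibited": (1, 1, 1, 10, 1),
        "ftd_prohibitive": (1, 1, 1, 1, 10),
        "equal_weights": (1, 1, 1, 1, 1),
    }
    return {name: CostScheme(*vec) for name, vec in raw.items()}


# ---------------------------------------------------------------------------
# internal indexed tree representation
# ---------------------------------------------------------------------------

class _Tree:
    """Rooted binary tree as parallel arrays (nodes in preorder)."""

    def __init__(self, dtree: dendropy.Tree):
        nodes = list(dtree.preorder_node_iter())
        self.n = len(nodes)
        self.index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = [-1] * self.n
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        self.tip_label: list[Optional[str]] = [None] * self.n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self.index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
            if nd.is_leaf():
                if nd.taxon is None:
                    raise ValueError("unlabeled tip")
                self.tip_label[i] = nd.taxon.label
        for i in range(self.n):
            k = len(self.children[i])
            if k not in (0, 2):
                raise ValueError("tree is not binary")
        self.root = 0
        self.tips = [i for i in range(self.n) if not self.children[i]]
        self.internals = [i for i in range(self.n) if self.children[i]]
        self.postorder = list(reversed(range(self.n)))  # preorder reversed
        # descendant tip sets
        self.desc_tips: list[frozenset[int]] = [frozenset()] * self.n
        for i in self.postorder:
            if not self.children[i]:
                self.desc_tips[i] = frozenset([i])
            else:
                s: frozenset[int] = frozenset()
                for c in self.children[i]:
                    s |= self.desc_tips[c]
                self.desc_tips[i] = s

    @property
    def n_tips(self) -> int:
        return len(self.tips)


@dataclass
class Tanglegram:
    """Host tree + symbiont tree + tip association links.

    ``links`` maps each symbiont tip label to the nonempty set of host tip
    labels it occurs in; a multi-host link encodes failure to diverge.
    """

    host: dendropy.Tree
    symbiont: dendropy.Tree
    links: dict[str, set[str]]

    def __post_init__(self) -> None:
        self._host = _Tree(self.host)
        self._symb = _Tree(self.symbiont)
        host_tips = {self._host.tip_label[i] for i in self._host.tips}
        symb_tips = {self._symb.tip_label[i] for i in self._symb.tips}
        if set(self.links) != symb_tips:
            missing = symb_tips - set(self.links)
            extra = set(self.links) - symb_tips
            raise ValueError(f"links do not cover symbiont tips exactly "
                             f"(missing={sorted(missing)}, extra={sorted(extra)})")
        for s, hs in self.links.items():
            if not hs:
                raise ValueError(f"symbiont tip {s!r} linked to no host")
            unknown = set(hs) - host_tips
            if unknown:
                raise ValueError(f"unknown host tips {sorted(unknown)} for {s!r}")

    @property
    def n_host_tips(self) -> int:
        return self._host.n_tips

    @property
    def n_symbiont_tips(self) -> int:
        return self._symb.n_tips


@dataclass
class Reconciliation:
    """One optimal mapping: per-node host placement, events, counts, cost."""

    placement: dict[str, str]
    event: dict[str, str]
    counts: EventCounts
    total_cost: float


@dataclass
class ReconciliationSummary:
    """Solver output: best cost, all distinct co-optimal event-count vectors,
    and one representative reconciliation."""

    best_cost: float
    counts_set: list[EventCounts]
    representative: Reconciliation
    n_timings_evaluated: int = 0

    def count_ranges(self) -> dict[str, tuple[int, int]]:
        """Per-event (min, max) across co-optima, the Table-style summary."""
        names = ["cospeciation", "duplication", "switch", "loss", "ftd"]
        cols = list(zip(*(c.as_tuple() for c in self.counts_set)))
        return {n: (min(col), max(col)) for n, col in zip(names, cols)}


@dataclass
class SolverConfig:
    generations: int = 10000
    population_size: int = 1000
    seed: int = 0
    exact_threshold: int = 8

    def __post_init__(self) -> None:
        if self.generations < 1 or self.population_size < 1 or self.exact_threshold < 1:
            raise ValueError("SolverConfig fields must be positive")


# ---------------------------------------------------------------------------
# DP over (symbiont node, host edge, time slice) for a fixed timing
# ---------------------------------------------------------------------------

class _Instance:
    """Preprocessed tanglegram shared across timings."""

    def __init__(self, tg: Tanglegram):
        self.host = tg._host
        self.symb = tg._symb
        host_label_to_tip = {self.host.tip_label[i]: i for i in self.host.tips}
        # symbiont tip -> frozenset of host tip node ids
        self.tip_hosts: dict[int, frozenset[int]] = {}
        for s in self.symb.tips:
            labels = tg.links[self.symb.tip_label[s]]
            self.tip_hosts[s] = frozenset(host_label_to_tip[l] for l in labels)
        # edges indexed by child host node; virtual root edge has child = root
        # and index host.n (placed last).
        self.n_edges = self.host.n + 1
        self.virtual_edge = self.host.n
        # tip fan costs: for each symbiont tip and host edge, the cost and
        # event increments of descending from that edge to exactly its hosts.
        self._fan_cache: dict[tuple[int, int], Optional[tuple[int, int]]] = {}

    def edge_child(self, e: int) -> int:
        return self.host.root if e == self.virtual_edge else e

    def fan(self, s: int, e: int) -> Optional[tuple[int, int]]:
        """(n_loss, n_ftd) for the tip lineage of symbiont tip ``s`` descending
        from host edge ``e`` to exactly its linked host tips, or None if they
        are not all reachable below ``e``."""
        key = (s, e)
        if key in self._fan_cache:
            return self._fan_cache[key]
        H = self.tip_hosts[s]
        v = self.edge_child(e)
        if not H <= self.host.desc_tips[v]:
            res: Optional[tuple[int, int]] = None
        else:
            res = self._fan_below(v, H)
        self._fan_cache[key] = res
        return res

    def _fan_below(self, v: int, H: frozenset[int]) -> tuple[int, int]:
        # v's subtree contains H (nonempty)
        if not self.host.children[v]:
            return (0, 0)  # v is the single host tip in H
        c1, c2 = self.host.children[v]
        H1 = H & self.host.desc_tips[c1]
        H2 = H & self.host.desc_tips[c2]
        if H1 and H2:
            l1, f1 = self._fan_below(c1, H1)
            l2, f2 = self._fan_below(c2, H2)
            return (l1 + l2, 1 + f1 + f2)
        child, Hc = (c1, H1) if H1 else (c2, H2)
        l, f = self._fan_below(child, Hc)
        return (1 + l, f)


def _linear_extensions(host: _Tree) -> Iterable[tuple[int, ...]]:
    """All total orders of internal host nodes consistent with ancestry."""
    internals = set(host.internals)
    parent = host.parent

    def extend(prefix: list[int], available: set[int]):
        if not available:
            yield tuple(prefix)
            return
        for v in sorted(available):
            newly = {c for c in host.children[v] if c in internals}
            yield from extend(prefix + [v], (available - {v}) | newly)

    yield from extend([], {host.root} if internals else set())


def _random_linear_extension(host: _Tree, rng: random.Random) -> tuple[int, ...]:
    internals = set(host.internals)
    prefix: list[int] = []
    available = {host.root} if internals else set()
    while available:
        v = rng.choice(sorted(available))
        prefix.append(v)
        available.remove(v)
        available |= {c for c in host.children[v] if c in internals}
    return tuple(prefix)


class _TimingDP:
    """Exact minimum-cost placement for one timing of the host internals."""

    def __init__(self, inst: _Instance, timing: tuple[int, ...], scheme: CostScheme):
        self.inst = inst
        self.scheme = scheme
        host = inst.host
        m = len(timing)
        self.m = m
        # rank[v] for internal host node v: 1..m (root first); tips rank m+1
        rank = {}
        for r, v in enumerate(timing, start=1):
            rank[v] = r
        for t in host.tips:
            rank[t] = m + 1
        self.rank = rank
        # edge e (child node id, or virtual): alive during slices
        # first_slice(e) = rank[parent], last_slice(e) = rank[child]-1.
        # Virtual root edge: slice 0 only.
        self.first: dict[int, int] = {inst.virtual_edge: 0}
        self.last: dict[int, int] = {inst.virtual_edge: 0}
        for v in range(host.n):
            if v == host.root:
                continue
            self.first[v] = rank[host.parent[v]]
            self.last[v] = rank[v] - 1
        self.alive: list[list[int]] = [[] for _ in range(m + 1)]
        self.alive[0] = [inst.virtual_edge]
        for e in range(host.n):
            if e == host.root:
                continue
            for r in range(self.first[e], self.last[e] + 1):
                self.alive[r].append(e)
        # DP tables: A[s] is dict (e, r) -> cost; bests[s][r] = (b1, e1, b2)
        symb = inst.symb
        self.A: list[dict[tuple[int, int], float]] = [dict() for _ in range(symb.n)]
        self.bests: list[list[tuple[float, int, float]]] = [
            [(_INF, -1, _INF)] * (m + 1) for _ in range(symb.n)
        ]
        for s in symb.postorder:
            self._fill(s)
        self.best_cost = self.A[symb.root].get((inst.virtual_edge, 0), _INF)

    def _options(self, s: int, e: int, r: int) -> list[tuple[float, tuple]]:
        """All (cost, move) options for state (s, e, r); move encodes the
        choice for backtracking."""
        inst, host, symb = self.inst, self.inst.host, self.inst.symb
        sch = self.scheme
        opts: list[tuple[float, tuple]] = []
        children = symb.children[s]
        if not children:
            fan = inst.fan(s, e)
            if fan is not None:
                n_loss, n_ftd = fan
                opts.append((n_loss * sch.loss + n_ftd * sch.failure_to_diverge,
                             ("tip", n_loss, n_ftd)))
            return opts
        a, b = children
        # duplication in this slice on this edge
        ca = self.A[a].get((e, r), _INF)
        cb = self.A[b].get((e, r), _INF)
        if ca < _INF and cb < _INF:
            opts.append((sch.duplication + ca + cb, ("dup",)))
        # duplication + host switch: one child stays, the other jumps to the
        # cheapest other edge alive in this slice
        for stay, move in ((a, b), (b, a)):
            cs = self.A[stay].get((e, r), _INF)
            if cs == _INF:
                continue
            b1, e1, b2 = self.bests[move][r]
            cm = b2 if e1 == e else b1
            target = -2 if e1 == e else e1  # -2: resolved during backtrack
            if cm < _INF:
                opts.append((sch.duplication_host_switch + cs + cm,
                             ("switch", stay, move)))
        # let time pass
        if r < self.last.get(e, -1):
            nxt = self.A[s].get((e, r + 1), _INF)
            if nxt < _INF:
                opts.append((nxt, ("wait",)))
        elif r == self.last.get(e, -1):
            v = inst.edge_child(e)
            if host.children[v]:
                f1, f2 = host.children[v]
                q = self.rank[v]
                # cospeciation at v
                for x, y in ((a, b), (b, a)):
                    cx = self.A[x].get((f1, q), _INF)
                    cy = self.A[y].get((f2, q), _INF)
                    if cx < _INF and cy < _INF:
                        opts.append((sch.cospeciation + cx + cy,
                                     ("cosp", x, f1, y, f2)))
                # cross into one child with a loss
                for f in (f1, f2):
                    cf = self.A[s].get((f, q), _INF)
                    if cf < _INF:
                        opts.append((sch.loss + cf, ("loss", f)))
            # v is a host tip: an internal symbiont node cannot pass it
        return opts

    def _fill(self, s: int) -> None:
        for r in range(self.m, -1, -1):
            for e in self.alive[r]:
                opts = self._options(s, e, r)
                if opts:
                    best = min(c for c, _ in opts)
                    if best < _INF:
                        self.A[s][(e, r)] = best
            # best / second-best over alive edges for switch targets
            b1, e1, b2 = _INF, -1, _INF
            for e in self.alive[r]:
                c = self.A[s].get((e, r), _INF)
                if c < b1:
                    b1, e1, b2 = c, e, b1
                elif c < b2:
                    b2 = c
            self.bests[s][r] = (b1, e1, b2)

    # -- backtracking ------------------------------------------------------

    def count_vectors(self, cap: int = 500) -> set[tuple[int, int, int, int, int]]:
        """All distinct event-count vectors among co-optimal reconciliations
        (capped to bound enumeration)."""
        memo: dict[tuple[int, int, int], set] = {}
        inst, symb = self.inst, self.inst.symb

        def rec(s: int, e: int, r: int) -> set:
            key = (s, e, r)
            if key in memo:
                return memo[key]
            target = self.A[s][(e, r)]
            out: set = set()
            for cost, move in self._options(s, e, r):
                if cost > target + 1e-9:
                    continue
                out |= self._move_counts(move, s, e, r, rec, target, cap)
                if len(out) >= cap:
                    break
            memo[key] = out
            return out

        root_states = rec(symb.root, inst.virtual_edge, 0)
        return set(itertools.islice(root_states, cap))

    def _move_counts(self, move, s, e, r, rec, target, cap) -> set:
        sch = self.scheme
        kind = move[0]
        if kind == "tip":
            return {(0, 0, 0, move[1], move[2])}
        if kind == "wait":
            return rec(s, e, r + 1)
        if kind == "loss":
            return {_add(v, (0, 0, 0, 1, 0))
                    for v in rec(s, move[1], self.rank[self.inst.edge_child(e)])}
        a, b = self.inst.symb.children[s]
        if kind == "dup":
            out = set()
            for va in rec(a, e, r):
                for vb in rec(b, e, r):
                    out.add(_add(_add(va, vb), (0, 1, 0, 0, 0)))
                    if len(out) >= cap:
                        return out
            return out
        if kind == "cosp":
            _, x, f1, y, f2 = move
            q = self.rank[self.inst.edge_child(e)]
            out = set()
            for vx in rec(x, f1, q):
                for vy in rec(y, f2, q):
                    out.add(_add(_add(vx, vy), (1, 0, 0, 0, 0)))
                    if len(out) >= cap:
                        return out
            return out
        if kind == "switch":
            _, stay, mover = move
            cs = self.A[stay][(e, r)]
            need = target - sch.duplication_host_switch - cs
            out = set()
            for f in self.alive[r]:
                if f == e:
                    continue
                cm = self.A[mover].get((f, r), _INF)
                if cm < _INF and abs(cm - need) < 1e-9:
                    for vs in rec(stay, e, r):
                        for vm in rec(mover, f, r):
                            out.add(_add(_add(vs, vm), (0, 0, 1, 0, 0)))
                            if len(out) >= cap:
                                return out
            return out
        raise AssertionError(kind)

    def representative(self) -> Reconciliation:
        """Backtrack one optimal reconciliation (first-found, deterministic)."""
        inst, host, symb = self.inst, self.inst.host, self.inst.symb
        placement: dict[str, str] = {}
        event: dict[str, str] = {}
        tally = [0, 0, 0, 0, 0]

        def host_pos_name(e: int, r: int) -> str:
            if e == inst.virtual_edge:
                return "root_stem"
            lab = host.tip_label[e]
            return f"edge_to_{lab}@slice{r}" if lab else f"edge_{e}@slice{r}"

        def symb_name(s: int) -> str:
            lab = symb.tip_label[s]
            return lab if lab else f"node_{s}"

        def walk(s: int, e: int, r: int) -> None:
            target = self.A[s][(e, r)]
            for cost, move in self._options(s, e, r):
                if cost > target + 1e-9:
                    continue
                kind = move[0]
                if kind == "tip":
                    placement[symb_name(s)] = host_pos_name(e, r)
                    tally[3] += move[1]
                    tally[4] += move[2]
                    return
                if kind == "wait":
                    walk(s, e, r + 1)
                    return
                if kind == "loss":
                    tally[3] += 1
                    walk(s, move[1], self.rank[inst.edge_child(e)])
                    return
                a, b = symb.children[s]
                placement[symb_name(s)] = host_pos_name(e, r)
                if kind == "dup":
                    event[symb_name(s)] = "duplication"
                    tally[1] += 1
                    walk(a, e, r)
                    walk(b, e, r)
                    return
                if kind == "cosp":
                    _, x, f1, y, f2 = move
                    event[symb_name(s)] = "cospeciation"
                    tally[0] += 1
                    q = self.rank[inst.edge_child(e)]
                    walk(x, f1, q)
                    walk(y, f2, q)
                    return
                if kind == "switch":
                    _, stay, mover = move
                    cs = self.A[stay][(e, r)]
                    need = target - self.scheme.duplication_host_switch - cs
                    for f in self.alive[r]:
                        if f != e and abs(self.A[mover].get((f, r), _INF) - need) < 1e-9:
                            event[symb_name(s)] = "duplication_host_switch"
                            tally[2] += 1
                            walk(stay, e, r)
                            walk(mover, f, r)
                            return
            raise AssertionError("backtracking failed")

        walk(symb.root, inst.virtual_edge, 0)
        counts = EventCounts(*tally)
        return Reconciliation(placement=placement, event=event, counts=counts,
                              total_cost=reconciliation_cost(counts, self.scheme))


def _add(u: tuple, v: tuple) -> tuple:
    return tuple(x + y for x, y in zip(u, v))


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _summarise(inst: _Instance, scheme: CostScheme,
               best_dps: list[_TimingDP], n_timings: int,
               enumerate_counts: bool) -> ReconciliationSummary:
    best_cost = best_dps[0].best_cost
    counts: set = set()
    if enumerate_counts:
        for dp in best_dps:
            counts |= dp.count_vectors()
    rep = best_dps[0].representative()
    if not enumerate_counts:
        counts = {rep.counts.as_tuple()}
    return ReconciliationSummary(
        best_cost=best_cost,
        counts_set=[EventCounts(*c) for c in sorted(counts)],
        representative=rep,
        n_timings_evaluated=n_timings,
    )


def reconcile_exact(tg: Tanglegram, scheme: CostScheme,
                    exact_threshold: int = 8,
                    enumerate_counts: bool = True) -> ReconciliationSummary:
    """Globally optimal reconciliation by enumerating every host timing.

    Raises if the instance exceeds ``exact_threshold`` tips on either side
    (use :func:`reconcile_search` instead).
    """
    if max(tg.n_host_tips, tg.n_symbiont_tips) > exact_threshold:
        raise ValueError(
            f"instance exceeds exact threshold ({exact_threshold} tips); "
            "use the heuristic solver (reconcile_search)")
    inst = _Instance(tg)
    best: list[_TimingDP] = []
    best_cost = _INF
    n = 0
    for timing in _linear_extensions(inst.host):
        n += 1
        dp = _TimingDP(inst, timing, scheme)
        if dp.best_cost < best_cost - 1e-9:
            best_cost = dp.best_cost
            best = [dp]
        elif abs(dp.best_cost - best_cost) < 1e-9:
            best.append(dp)
    if not best or best_cost == _INF:
        raise ValueError("no feasible reconciliation (malformed tanglegram)")
    return _summarise(inst, scheme, best, n, enumerate_counts)


def reconcile_search(tg: Tanglegram, scheme: CostScheme,
                     config: Optional[SolverConfig] = None,
                     enumerate_counts: bool = True) -> ReconciliationSummary:
    """Heuristic search over host timings (exact DP per timing).

    A seeded (mu + lambda)-style evolutionary search over linear extensions of
    the host internal-node partial order: candidates are mutated by adjacent
    transpositions that respect ancestry, and the best-known timings are kept.
    On instances small enough for :func:`reconcile_exact`, the search attains
    the exact optimum because the timing space is tiny.
    """
    config = config or SolverConfig()
    inst = _Instance(tg)
    rng = random.Random(config.seed)
    internals = set(inst.host.internals)

    def valid(order: tuple[int, ...]) -> bool:
        pos = {v: i for i, v in enumerate(order)}
        return all(pos[inst.host.parent[v]] < pos[v]
                   for v in order if v != inst.host.root)

    cache: dict[tuple[int, ...], float] = {}
    dps: dict[tuple[int, ...], _TimingDP] = {}

    def evaluate(order: tuple[int, ...]) -> float:
        if order not in cache:
            dp = _TimingDP(inst, order, scheme)
            cache[order] = dp.best_cost
            dps[order] = dp
        return cache[order]

    def mutate(order: tuple[int, ...]) -> tuple[int, ...]:
        if len(order) < 2:
            return order
        for _ in range(10):
            i = rng.randrange(len(order) - 1)
            cand = list(order)
            cand[i], cand[i + 1] = cand[i + 1], cand[i]
            cand_t = tuple(cand)
            if valid(cand_t):
                return cand_t
        return order

    pop_size = min(config.population_size, 64)
    population = {_random_linear_extension(inst.host, rng) for _ in range(pop_size)}
    for order in population:
        evaluate(order)
    generations = min(config.generations, 200)
    stagnant = 0
    best_cost = min(cache.values())
    for _ in range(generations):
        ranked = sorted(population, key=lambda o: (cache[o], o))
        parents = ranked[:max(2, len(ranked) // 2)]
        offspring = {mutate(rng.choice(parents)) for _ in range(pop_size)}
        offspring.add(_random_linear_extension(inst.host, rng))
        for order in offspring:
            evaluate(order)
        population = set(sorted(population | offspring,
                                key=lambda o: (cache[o], o))[:pop_size])
        new_best = min(cache.values())
        if new_best < best_cost - 1e-9:
            best_cost, stagnant = new_best, 0
        else:
            stagnant += 1
        if stagnant >= 25:
            break
    best_orders = [o for o, c in cache.items() if abs(c - best_cost) < 1e-9]
    best_dps = [dps[o] for o in best_orders]
    return _summarise(inst, scheme, best_dps, len(cache), enumerate_counts)


# ---------------------------------------------------------------------------
# random-tree significance test
# ---------------------------------------------------------------------------

def random_binary_topology(labels: Sequence[str], rng: random.Random) -> dendropy.Tree:
    """Uniform random rooted binary labeled topology (PDA model), built by
    inserting each leaf on a uniformly chosen edge (Remy-style insertion)."""
    if len(labels) < 1:
        raise ValueError("need at least one label")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    order = list(labels)
    rng.shuffle(order)
    first = tree.seed_node
    first.taxon = taxa.new_taxon(order[0])
    nodes = [first]  # nodes whose subtending edge can host an insertion
    for lab in order[1:]:
        attach = rng.choice(nodes)
        new_internal = dendropy.Node()
        new_leaf = dendropy.Node()
        new_leaf.taxon = taxa.new_taxon(lab)
        parent = attach.parent_node
        if parent is None:
            tree.seed_node = new_internal
        else:
            parent.remove_child(attach)
            parent.add_child(new_internal)
        new_internal.add_child(attach)
        new_internal.add_child(new_leaf)
        nodes.extend([new_internal, new_leaf])
    for edge in tree.preorder_edge_iter():
        edge.length = 1.0
    return tree


@dataclass
class RandomTreeTestResult:
    observed_cost: float
    null_costs: list[float]
    p_value: float
    n_samples: int


def random_tree_test(tg: Tanglegram, scheme: CostScheme,
                     n_samples: int = 500,
                     config: Optional[SolverConfig] = None,
                     null: str = "topology") -> RandomTreeTestResult:
    """Significance of the reconstruction cost against random symbiont trees.

    ``null='topology'`` draws uniform random binary topologies on the same
    symbiont tip label set (links retained); ``null='shuffle'`` instead
    permutes the tip labels of the observed symbiont topology.  Each sample is
    solved under identical settings and p = (1 + #{null <= observed}) /
    (n_samples + 1).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if null not in ("topology", "shuffle"):
        raise ValueError("null must be 'topology' or 'shuffle'")
    config = config or SolverConfig()
    rng = random.Random(config.seed)

    def solve(t: Tanglegram) -> float:
        if max(t.n_host_tips, t.n_symbiont_tips) <= config.exact_threshold:
            return reconcile_exact(t, scheme, config.exact_threshold,
                                   enumerate_counts=False).best_cost
        sub = SolverConfig(generations=config.generations,
                           population_size=config.population_size,
                           seed=rng.randrange(2**31), exact_threshold=config.exact_threshold)
        return reconcile_search(t, scheme, sub, enumerate_counts=False).best_cost

    observed = solve(tg)
    labels = sorted(tg.links)
    null_costs = []
    for _ in range(n_samples):
        if null == "topology":
            rand_symb = random_binary_topology(labels, rng)
            links = dict(tg.links)
        else:
            # shuffle which host set each symbiont tip carries, topology fixed
            perm = list(labels)
            rng.shuffle(perm)
            rand_symb = tg.symbiont
            links = {s: set(tg.links[p]) for s, p in zip(labels, perm)}
        null_tg = Tanglegram(host=tg.host, symbiont=rand_symb, links=links)
        null_costs.append(solve(null_tg))
    k = sum(1 for c in null_costs if c <= observed + 1e-9)
    p = (1 + k) / (n_samples + 1)
    return RandomTreeTestResult(observed_cost=observed, null_costs=null_costs,
                                p_value=p, n_samples=n_samples)
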