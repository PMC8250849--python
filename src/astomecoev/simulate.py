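"""Synthetic tanglegrams, alignments and occurrence tables with known truth.

The cophylogeny generator evolves symbiont lineages top-down along a timed
Yule host tree.  At each host speciation an incumbent lineage cospeciates,
follows both host children without diverging (failure to diverge, producing a
multi-host tip), or follows one child (a loss).  Along host edges,
duplications and duplication+host-switch events arrive as Poisson processes;
a switching daughter jumps to a uniformly chosen contemporaneous host edge.
A lineage that has failed to diverge is already committed to multiple hosts
and undergoes no further divergence events; at later host speciations it
either spans the speciation again (another failure to diverge) or follows one
child (a loss).  Every event is logged, so the generating history's exact
event counts — and hence its reconciliation cost under any scheme — are known.
"""

from __future__ import annotations

import heapq
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .reconcile import EventCounts, Tanglegram
from .seqio import MultipleAlignment
from .diagnostics import OccurrenceTable

__all__ = [
    "SimConfig",
    "SimulatedCophylogeny",
    "simulate_host_tree",
    "simulate_cophylogeny",
    "simulate_alignment",
    "simulate_occurrence",
    "write_tanglegram",
]


@dataclass
class SimConfig:
    """Parameters of the cophylogeny generator.

    ``cospeciation_prob``, ``ftd_prob`` and ``loss_prob`` are the symbiont's
    behaviour at a host speciation and must sum to 1; ``duplication_rate`` and
    ``switch_rate`` are per-lineage Poisson rates per unit host-tree time
    (the host root is at depth 1).
    """

    n_host_tips: int = 8
    cospeciation_prob: float = 0.6
    duplication_rate: float = 0.5
    switch_rate: float = 0.5
    loss_prob: float = 0.3
    ftd_prob: float = 0.1
    seq_length: int = 1000
    subst_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_host_tips < 2:
            raise ValueError("n_host_tips must be >= 2")
        for name in ("cospeciation_prob", "loss_prob", "ftd_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(self.cospeciation_prob + self.loss_prob + self.ftd_prob - 1.0) > 1e-9:
            raise ValueError("cospeciation_prob + loss_prob + ftd_prob must be 1")
        if self.duplication_rate < 0 or self.switch_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.seq_length < 1:
            raise ValueError("seq_length must be positive")
        if self.subst_scale < 0:
            raise ValueError("subst_scale must be nonnegative")


@dataclass
class SimulatedCophylogeny:
    tanglegram: Tanglegram
    true_events: EventCounts
    event_log: list[tuple[str, str, int]]  # (event kind, host location, lineage id)


def simulate_host_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) host tree with ``n_tips`` extant tips, rescaled so the
    root is at depth 1; tips are labeled H1..Hn."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng)
    tree.seed_node.edge.length = None
    # the pure-birth simulation stops at the n-th speciation; extend the tips
    # by the waiting time to the (unrealised) next speciation so terminal
    # branches are not degenerate
    extra = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # rescale to root depth 1
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda l: l.taxon.label), start=1):
        leaf.taxon.label = f"H{i}"
    return tree


class _Lineage:
    __slots__ = ("lid", "edges", "frozen", "symb_node", "born")

    def __init__(self, lid: int, edges: set, frozen: bool, symb_node, born: float):
        self.lid = lid
        self.edges = edges      # set of host nodes (edge = edge above node)
        self.frozen = frozen    # True once failure-to-diverge happened
        self.symb_node = symb_node
        self.born = born


def simulate_cophylogeny(config: SimConfig) -> SimulatedCophylogeny:
    """Evolve symbiont lineages along a simulated host tree; returns the
    tanglegram together with the generating event history."""
    rng = random.Random(config.seed)
    host = simulate_host_tree(config.n_host_tips, rng.randrange(2**31))

    # host node times (root at 0, tips at 1) and chronology of speciations
    time_of: dict[int, float] = {}
    label_of: dict[int, str] = {}
    node_by_id: dict[int, dendropy.Node] = {}
    preorder_idx: dict[int, int] = {}
    for k, nd in enumerate(host.preorder_node_iter()):
        t = nd.distance_from_root()
        time_of[id(nd)] = t
        node_by_id[id(nd)] = nd
        preorder_idx[id(nd)] = k
        label_of[id(nd)] = nd.taxon.label if nd.is_leaf() else f"hnode{k}@{t:.4f}"
    speciations = sorted(
        ((time_of[id(nd)], preorder_idx[id(nd)], id(nd))
         for nd in host.preorder_node_iter() if not nd.is_leaf()))
    speciations = [(t, nid) for t, _, nid in speciations]

    def alive_edges(t: float) -> list[int]:
        """Host nodes whose subtending edge spans time t."""
        out = []
        for nid, nd in node_by_id.items():
            if nd.parent_node is None:
                continue
            if time_of[id(nd.parent_node)] < t <= time_of[nid]:
                out.append(nid)
        return sorted(out, key=lambda nid: label_of[nid])

    # growing symbiont tree: nodes are dicts
    symb_nodes: list[dict] = []

    def new_symb_node(parent: Optional[int], t: float) -> int:
        symb_nodes.append({"parent": parent, "time": t, "children": [], "label": None})
        idx = len(symb_nodes) - 1
        if parent is not None:
            symb_nodes[parent]["children"].append(idx)
        return idx

    event_log: list[tuple[str, str, int]] = []
    tally = {"cospeciation": 0, "duplication": 0, "duplication_host_switch": 0,
             "loss": 0, "failure_to_diverge": 0}

    def log(kind: str, where: str, lid: int) -> None:
        event_log.append((kind, where, lid))
        tally[kind] += 1

    next_lid = [0]

    def make_lineage(edges: set, frozen: bool, parent_symb: Optional[int],
                     t: float) -> _Lineage:
        lin = _Lineage(next_lid[0], edges, frozen, new_symb_node(parent_symb, t), t)
        next_lid[0] += 1
        return lin

    root_children = {id(c) for c in host.seed_node.child_nodes()}
    # incumbent lineage sits on the host root stem; first speciation is the root
    stem = make_lineage({id(host.seed_node)}, False, None, 0.0)
    lineages: list[_Lineage] = [stem]
    total_rate = config.duplication_rate + config.switch_rate

    def next_event_time(t: float) -> float:
        if total_rate <= 0:
            return math.inf
        return t + rng.expovariate(total_rate)

    # priority queue of per-lineage duplication/switch candidate times
    heap: list[tuple[float, int]] = []
    by_lid = {stem.lid: stem}
    heapq.heappush(heap, (next_event_time(0.0), stem.lid))

    def drain_poisson_until(t_end: float) -> None:
        # per-lineage duplication/switch events strictly before t_end
        while heap and heap[0][0] < t_end:
            t_ev, lid = heapq.heappop(heap)
            lin = by_lid.get(lid)
            if lin is None or lin.frozen:
                continue
            choose_dup = (total_rate > 0 and
                          rng.random() < config.duplication_rate / total_rate)
            (edge_nid,) = lin.edges
            if choose_dup:
                node = new_symb_node(lin.symb_node, t_ev)
                lin.symb_node = node  # reuse dict entry as divergence point
                d1 = make_lineage({edge_nid}, False, node, t_ev)
                d2 = make_lineage({edge_nid}, False, node, t_ev)
                lineages.remove(lin)
                del by_lid[lin.lid]
                lineages.extend([d1, d2])
                by_lid[d1.lid] = d1
                by_lid[d2.lid] = d2
                log("duplication", label_of[edge_nid], lin.lid)
                heapq.heappush(heap, (next_event_time(t_ev), d1.lid))
                heapq.heappush(heap, (next_event_time(t_ev), d2.lid))
            else:
                targets = [e for e in alive_edges(t_ev) if e != edge_nid]
                if targets:
                    node = new_symb_node(lin.symb_node, t_ev)
                    lin.symb_node = node
                    stay = make_lineage({edge_nid}, False, node, t_ev)
                    jump = make_lineage({rng.choice(targets)}, False, node, t_ev)
                    lineages.remove(lin)
                    del by_lid[lin.lid]
                    lineages.extend([stay, jump])
                    by_lid[stay.lid] = stay
                    by_lid[jump.lid] = jump
                    log("duplication_host_switch", label_of[edge_nid], lin.lid)
                    heapq.heappush(heap, (next_event_time(t_ev), stay.lid))
                    heapq.heappush(heap, (next_event_time(t_ev), jump.lid))
                else:
                    heapq.heappush(heap, (next_event_time(t_ev), lid))

    for t_spec, spec_nid in speciations:
        drain_poisson_until(t_spec)
        # the speciation: every lineage occupying the splitting edge reacts
        spec_node = node_by_id[spec_nid]
        child_ids = [id(c) for c in spec_node.child_nodes()]
        where = label_of[spec_nid]
        for lin in list(lineages):
            if spec_nid not in lin.edges:
                continue
            if lin.frozen:
                denom = config.ftd_prob + config.loss_prob
                p_span = config.ftd_prob / denom if denom > 0 else 0.0
                lin.edges.discard(spec_nid)
                if rng.random() < p_span:
                    lin.edges.update(child_ids)
                    log("failure_to_diverge", where, lin.lid)
                else:
                    lin.edges.add(rng.choice(child_ids))
                    log("loss", where, lin.lid)
                continue
            u = rng.random()
            if u < config.cospeciation_prob:
                node = new_symb_node(lin.symb_node, t_spec)
                lin.symb_node = node
                d1 = make_lineage({child_ids[0]}, False, node, t_spec)
                d2 = make_lineage({child_ids[1]}, False, node, t_spec)
                lineages.remove(lin)
                del by_lid[lin.lid]
                lineages.extend([d1, d2])
                by_lid[d1.lid] = d1
                by_lid[d2.lid] = d2
                log("cospeciation", where, lin.lid)
                heapq.heappush(heap, (next_event_time(t_spec), d1.lid))
                heapq.heappush(heap, (next_event_time(t_spec), d2.lid))
            elif u < config.cospeciation_prob + config.ftd_prob:
                lin.edges = set(child_ids)
                lin.frozen = True
                log("failure_to_diverge", where, lin.lid)
            else:
                lin.edges = {rng.choice(child_ids)}
                log("loss", where, lin.lid)
    drain_poisson_until(1.0)

    if not lineages:
        raise RuntimeError("symbiont extinct (unreachable under this event model)")

    # finalize symbiont tips and links
    links: dict[str, set[str]] = {}
    for k, lin in enumerate(sorted(lineages, key=lambda l: l.lid), start=1):
        label = f"S{k}"
        nd = symb_nodes[lin.symb_node]
        if nd["children"]:
            # divergence node was reused; attach a fresh tip
            tip = new_symb_node(lin.symb_node, 1.0)
            symb_nodes[tip]["label"] = label
        else:
            nd["label"] = label
            nd["tip_time"] = 1.0
        links[label] = {node_by_id[e].taxon.label for e in lin.edges}

    symb_tree = _build_dendropy_tree(symb_nodes)
    tg = Tanglegram(host=host, symbiont=symb_tree, links=links)
    counts = EventCounts(
        n_cospeciation=tally["cospeciation"],
        n_duplication=tally["duplication"],
        n_switch=tally["duplication_host_switch"],
        n_loss=tally["loss"],
        n_ftd=tally["failure_to_diverge"],
    )
    return SimulatedCophylogeny(tanglegram=tg, true_events=counts, event_log=event_log)


def _build_dendropy_tree(symb_nodes: list[dict]) -> dendropy.Tree:
    """Convert the simulator's node records into a dendropy tree, suppressing
    unary pass-through nodes."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(idx: int) -> dendropy.Node:
        rec = symb_nodes[idx]
        children = rec["children"]
        if len(children) == 1:
            return build(children[0])
        node = dendropy.Node()
        t = rec.get("tip_time", rec["time"])
        node._sim_time = t
        if not children:
            node.taxon = taxa.new_taxon(rec["label"])
            node._sim_time = 1.0
        for c in children:
            child = build(c)
            node.add_child(child)
            child.edge.length = max(child._sim_time - node._sim_time, 0.0)
        return node

    roots = [i for i, rec in enumerate(symb_nodes) if rec["parent"] is None]
    assert len(roots) == 1
    tree.seed_node = build(roots[0])
    return tree


def simulate_alignment(tree: dendropy.Tree, seq_length: int, seed: int,
                       prefix_root: Optional[str] = None) -> MultipleAlignment:
    """Gapless alignment evolved along the tree under Jukes-Cantor.

    Branch lengths are expected substitutions per site; per site and branch
    the substitution follows the JC transition probabilities, so the expected
    p-distance between two tips at path length d is (3/4)(1 - exp(-4d/3)).
    """
    if seq_length < 1:
        raise ValueError("seq_length must be positive")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs: dict[str, np.ndarray] = {}

    def evolve(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            d = child.edge.length or 0.0
            p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            child_seq = seq.copy()
            hit = rng.random(seq_length) < p_change
            if hit.any():
                # a changed site moves to one of the three other states
                shift = rng.integers(1, 4, size=int(hit.sum()))
                child_seq[hit] = (child_seq[hit] + shift) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                evolve(child, child_seq)

    root = tree.seed_node
    if root.is_leaf():
        seqs[root.taxon.label] = root_seq
    else:
        evolve(root, root_seq)
    alpha = np.array(list("ACGT"))
    ids = sorted(seqs)
    rows = ["".join(alpha[seqs[i]]) for i in ids]
    return MultipleAlignment(ids=ids, rows=rows, alphabet="dna")


def simulate_occurrence(n_hosts: int, n_symbionts: int, prevalence: float,
                        seed: int, mean_examined: int = 30) -> OccurrenceTable:
    """Per-host examined/infected counts and a host-to-symbiont incidence map.

    Examined counts are Poisson around ``mean_examined`` (at least 1), the
    infected count is binomial at the given prevalence, and each host with at
    least one infection carries one or two symbiont species, emulating the
    small per-host astome communities seen in earthworms.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if n_hosts < 1 or n_symbionts < 1:
        raise ValueError("need at least one host and one symbiont")
    rng = np.random.default_rng(seed)
    examined = np.maximum(rng.poisson(mean_examined, size=n_hosts), 1)
    infected = rng.binomial(examined, prevalence)
    hosts = [f"H{i}" for i in range(1, n_hosts + 1)]
    symbionts = [f"S{j}" for j in range(1, n_symbionts + 1)]
    incidence: dict[str, set[str]] = {}
    for i, h in enumerate(hosts):
        if infected[i] > 0:
            k = int(rng.integers(1, min(2, n_symbionts) + 1))
            chosen = rng.choice(n_symbionts, size=k, replace=False)
            incidence[h] = {symbionts[int(c)] for c in chosen}
        else:
            incidence[h] = set()
    return OccurrenceTable(
        hosts=hosts,
        examined={h: int(e) for h, e in zip(hosts, examined)},
        infected={h: int(x) for h, x in zip(hosts, infected)},
        symbionts=incidence,
    )


def write_tanglegram(sim: SimulatedCophylogeny, out_dir: str | Path,
                     stem: str = "sim") -> dict[str, str]:
    """Write host/symbiont Newick, a links TSV and a JSON event-log sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "host": str(out / f"{stem}_host.nwk"),
        "symbiont": str(out / f"{stem}_symbiont.nwk"),
        "links": str(out / f"{stem}_links.tsv"),
        "events": str(out / f"{stem}_events.json"),
    }
    sim.tanglegram.host.write(path=paths["host"], schema="newick")
    sim.tanglegram.symbiont.write(path=paths["symbiont"], schema="newick")
    with open(paths["links"], "w") as fh:
        fh.write("symbiont_tip\thost_tips\n")
        for s in sorted(sim.tanglegram.links):
            fh.write(f"{s}\t{','.join(sorted(sim.tanglegram.links[s]))}\n")
    with open(paths["events"], "w") as fh:
        json.dump({
            "true_events": dict(zip(
                ["cospeciation", "duplication", "switch", "loss", "ftd"],
                sim.true_events.as_tuple())),
            "event_log": [list(e) for e in sim.event_log],
        }, fh, indent=1)
    return paths
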