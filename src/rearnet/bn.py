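"""Bayesian-network structure learning over discrete variables.

Networks are scored with the Bayesian Dirichlet (BDeu) marginal likelihood:
for a child with r states and q parent configurations, hyperparameters
``a_jk = ess / (q * r)`` and ``a_j = ess / q``, the local log score is

    sum_j [ lgamma(a_j) - lgamma(a_j + N_j)
            + sum_k ( lgamma(a_jk + N_jk) - lgamma(a_jk) ) ]

computed in log-gamma space; unobserved parent configurations contribute
zero.  The total network score is the sum of local scores (decomposable),
and BDeu is score-equivalent: Markov-equivalent DAGs receive the same score.

The search is simulated annealing over add / delete / reverse moves,
proposing uniformly over the currently legal moves (acyclic, within the
parent-count bound, never a blocked edge), accepting a score-worsening move
of size ``delta`` with probability ``exp(delta / T)`` under a geometric
cooling schedule.  An exhaustive enumeration over all DAGs is provided as an
oracle for small variable sets.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

from .blocklist import EdgeBlocklist
from .discretize import DiscreteDataset
from .errors import EnumerationLimitError, ValidationError

import logging

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@dataclass
class DAGNetwork:
    """Directed acyclic network with its log BDeu score."""

    nodes: list[str]
    arities: dict[str, int]
    edges: set[tuple[str, str]]
    score: float

    def parents(self, node: str) -> set[str]:
        return {u for u, v in self.edges if v == node}

    def children(self, node: str) -> set[str]:
        return {v for u, v in self.edges if u == node}

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def to_dot(self, snp_nodes=()) -> str:
        lines = ["digraph network {"]
        for n in self.nodes:
            shape = "ellipse" if n not in snp_nodes else "box"
            color = "lightgrey" if n not in snp_nodes else "yellow"
            lines.append(
                f'  "{n}" [shape={shape}, style=filled, fillcolor={color}];'
            )
        for u, v in self.sorted_edges():
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


@dataclass
class SAConfig:
    """Simulated-annealing search parameters.

    ``initial_temperature=None`` calibrates the start temperature in a
    1,000-proposal warm-up so that roughly half of the worsening moves seen
    there would be accepted.  Cooling is geometric: T is multiplied by
    ``cooling_factor`` every ``moves_per_temperature`` proposals.
    """

    initial_temperature: float | None = None
    cooling_factor: float = 0.95
    moves_per_temperature: int = 200
    max_iterations: int | None = 200_000
    time_budget: float | None = None
    restarts: int = 1
    seed: int = 0
    equivalent_sample_size: float = 1.0
    max_parents: int = 4
    random_init: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_factor < 1.0:
            raise ValidationError("cooling_factor must be strictly in (0, 1)")
        if self.max_iterations is None and self.time_budget is None:
            raise ValidationError(
                "at least one of max_iterations / time_budget must be set"
            )
        if self.equivalent_sample_size <= 0:
            raise ValidationError("equivalent sample size must be positive")
        if self.max_parents < 1:
            raise ValidationError("max_parents must be >= 1")


def bde_local_score(
    child: str, parents, data: DiscreteDataset, ess: float = 1.0
) -> float:
    """Log BDeu local score of one child given a parent set."""
    parents = list(parents)
    if child in parents:
        raise ValidationError(f"{child!r} cannot be its own parent")
    if ess <= 0:
        raise ValidationError("equivalent sample size must be positive")
    arity = data.arity
    y = data.codes(child)
    r = arity[child]
    if len(y) == 0:
        return 0.0
    if parents:
        dims = [arity[p] for p in parents]
        config = np.ravel_multi_index(
            tuple(data.codes(p) for p in parents), dims
        )
        q = int(np.prod(dims))
    else:
        config = np.zeros(len(y), dtype=np.int64)
        q = 1
    return _bde_from_counts(config, y, q, r, ess)


def _bde_from_counts(config, y, q: int, r: int, ess: float) -> float:
    n_jk = np.bincount(config * r + y, minlength=q * r).reshape(q, r)
    a_jk = ess / (q * r)
    a_j = ess / q
    n_j = n_jk.sum(axis=1)
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j))
        + np.sum(gammaln(a_jk + n_jk)) - q * r * gammaln(a_jk)
    )
    return score


class Scorer:
    """Cached BDeu local scores over a fixed dataset."""

    def __init__(self, data: DiscreteDataset, ess: float = 1.0):
        if ess <= 0:
            raise ValidationError("equivalent sample size must be positive")
        self.nodes = data.columns
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.codes = np.stack([data.codes(c) for c in self.nodes], axis=1)
        self.arity = data.arities()
        self.ess = ess
        self._cache: dict[tuple[int, frozenset], float] = {}

    def local(self, child: int, parents: frozenset) -> float:
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        ps = sorted(parents)
        y = self.codes[:, child]
        r = int(self.arity[child])
        if ps:
            dims = [int(self.arity[p]) for p in ps]
            config = np.ravel_multi_index(
                tuple(self.codes[:, p] for p in ps), dims
            )
            q = int(np.prod(dims))
        else:
            config = np.zeros(self.codes.shape[0], dtype=np.int64)
            q = 1
        score = _bde_from_counts(config, y, q, r, self.ess)
        self._cache[key] = score
        return score

    def network_score(self, parent_sets: list[frozenset]) -> float:
        return sum(self.local(i, ps) for i, ps in enumerate(parent_sets))


def is_acyclic(edges, nodes) -> bool:
    """True iff a topological ordering of ``nodes`` exists under ``edges``."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return nx.is_directed_acyclic_graph(g)


def enumerate_dags(n_nodes: int, allowed=None, max_parents: int | None = None):
    """Yield every DAG (as a frozenset of (parent, child) index pairs) over
    ``n_nodes`` labelled nodes, honoring an allowed-edge mask and a parent
    bound.  Recursion over the candidate edge list with acyclicity pruning."""
    if n_nodes > 6:
        raise EnumerationLimitError(
            f"exhaustive enumeration limited to 6 variables, got {n_nodes}"
        )
    candidates = [
        (u, v)
        for u in range(n_nodes)
        for v in range(n_nodes)
        if u != v and (allowed is None or (u, v) in allowed)
    ]
    adj: list[set[int]] = [set() for _ in range(n_nodes)]
    indeg = [0] * n_nodes
    chosen: list[tuple[int, int]] = []

    def reaches(src: int, dst: int) -> bool:
        stack, seen = [src], {src}
        while stack:
            x = stack.pop()
            if x == dst:
                return True
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return False

    def rec(i: int):
        if i == len(candidates):
            yield frozenset(chosen)
            return
        yield from rec(i + 1)
        u, v = candidates[i]
        if max_parents is not None and indeg[v] >= max_parents:
            return
        if reaches(v, u):
            return
        adj[u].add(v)
        indeg[v] += 1
        chosen.append((u, v))
        yield from rec(i + 1)
        adj[u].remove(v)
        indeg[v] -= 1
        chosen.pop()

    yield from rec(0)


def exhaustive_search(
    data: DiscreteDataset,
    blocklist: EdgeBlocklist | None = None,
    ess: float = 1.0,
    max_parents: int = 4,
) -> DAGNetwork:
    """Global BDeu maximum by enumerating every admissible DAG (<= 6 vars).

    Ties are broken by fewest edges, then lexicographically on the sorted
    edge list.
    """
    nodes = data.columns
    n = len(nodes)
    if n > 6:
        raise EnumerationLimitError(
            f"exhaustive search limited to 6 variables, got {n}"
        )
    scorer = Scorer(data, ess)
    blocked = _blocked_matrix(nodes, blocklist)
    allowed = {
        (u, v)
        for u in range(n)
        for v in range(n)
        if u != v and not blocked[u, v]
    }
    best = None
    for edge_set in enumerate_dags(n, allowed=allowed, max_parents=max_parents):
        parent_sets = [frozenset() for _ in range(n)]
        by_child: dict[int, set[int]] = {}
        for u, v in edge_set:
            by_child.setdefault(v, set()).add(u)
        for v, ps in by_child.items():
            parent_sets[v] = frozenset(ps)
        score = scorer.network_score(parent_sets)
        names = sorted((nodes[u], nodes[v]) for u, v in edge_set)
        key = (-score, len(edge_set), names)
        if best is None or key < best[0]:
            best = (key, score, set((nodes[u], nodes[v]) for u, v in edge_set))
    assert best is not None
    arity = data.arity
    return DAGNetwork(
        nodes=list(nodes),
        arities={c: int(arity[c]) for c in nodes},
        edges=best[2],
        score=best[1],
    )


def _blocked_matrix(nodes, blocklist: EdgeBlocklist | None) -> np.ndarray:
    n = len(nodes)
    index = {name: i for i, name in enumerate(nodes)}
    blocked = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(blocked, True)
    if blocklist is not None:
        for u, v in blocklist.edges:
            if u not in index or v not in index:
                raise ValidationError(
                    f"blocklist edge ({u!r}, {v!r}) references unknown variable"
                )
            blocked[index[u], index[v]] = True
    return blocked


def _closure(adj: np.ndarray) -> np.ndarray:
    """Reachability by paths of length >= 1 (boolean transitive closure)."""
    reach = adj.copy()
    while True:
        nxt = reach | (reach.astype(np.uint8) @ adj.astype(np.uint8) > 0)
        if (nxt == reach).all():
            return reach
        reach = nxt


class _SAState:
    """Mutable annealing state: adjacency, reachability, local scores."""

    def __init__(self, scorer: Scorer, blocked: np.ndarray, max_parents: int):
        self.scorer = scorer
        self.blocked = blocked
        self.max_parents = max_parents
        n = len(scorer.nodes)
        self.n = n
        self.adj = np.zeros((n, n), dtype=bool)
        self.reach = np.zeros((n, n), dtype=bool)
        self.parent_sets = [frozenset() for _ in range(n)]
        self.local = np.array(
            [scorer.local(i, frozenset()) for i in range(n)]
        )

    @property
    def score(self) -> float:
        return float(self.local.sum())

    def legal_moves(self):
        indeg = self.adj.sum(axis=0)
        room = indeg < self.max_parents
        add = ~self.adj & ~self.blocked & ~self.reach.T & room[None, :]
        delete = self.adj
        alt = (self.adj.astype(np.uint8) @ self.reach.astype(np.uint8)) > 0
        reverse = self.adj & ~self.blocked.T & ~alt & room[:, None]
        return add, delete, reverse

    def delta(self, kind: str, u: int, v: int) -> tuple[float, list]:
        """Score change and the (node, new parent set, new local) updates."""
        updates = []
        if kind == "add":
            ps = self.parent_sets[v] | {u}
            updates.append((v, ps, self.scorer.local(v, ps)))
        elif kind == "delete":
            ps = self.parent_sets[v] - {u}
            updates.append((v, ps, self.scorer.local(v, ps)))
        else:  # reverse u->v  =>  v->u
            ps_v = self.parent_sets[v] - {u}
            ps_u = self.parent_sets[u] | {v}
            updates.append((v, ps_v, self.scorer.local(v, ps_v)))
            updates.append((u, ps_u, self.scorer.local(u, ps_u)))
        delta = sum(new - self.local[node] for node, _, new in updates)
        return float(delta), updates

    def apply(self, kind: str, u: int, v: int, updates) -> None:
        if kind == "add":
            self.adj[u, v] = True
            # paths through the new edge: (x ->* u or x=u) then (v ->* y or y=v)
            src = self.reach[:, u].copy()
            src[u] = True
            dst = self.reach[v, :].copy()
            dst[v] = True
            self.reach |= np.outer(src, dst)
        elif kind == "delete":
            self.adj[u, v] = False
            self.reach = _closure(self.adj)
        else:
            self.adj[u, v] = False
            self.adj[v, u] = True
            self.reach = _closure(self.adj)
        for node, ps, new in updates:
            self.parent_sets[node] = ps
            self.local[node] = new

    def edge_names(self) -> set[tuple[str, str]]:
        nodes = self.scorer.nodes
        us, vs = np.nonzero(self.adj)
        return {(nodes[u], nodes[v]) for u, v in zip(us, vs)}


def _random_init(state: _SAState, rng) -> None:
    """Seed the state with a handful of random legal additions."""
    target = rng.integers(0, state.n + 1)
    for _ in range(int(target)):
        add, _, _ = state.legal_moves()
        options = np.argwhere(add)
        if options.size == 0:
            return
        u, v = options[rng.integers(len(options))]
        delta, updates = state.delta("add", int(u), int(v))
        state.apply("add", int(u), int(v), updates)


_KINDS = ("add", "delete", "reverse")


def _propose(state: _SAState, rng):
    add, delete, reverse = state.legal_moves()
    counts = (int(add.sum()), int(delete.sum()), int(reverse.sum()))
    total = sum(counts)
    if total == 0:
        return None
    pick = int(rng.integers(total))
    for kind, mask, c in zip(_KINDS, (add, delete, reverse), counts):
        if pick < c:
            flat = np.flatnonzero(mask.ravel())[pick]
            u, v = divmod(int(flat), state.n)
            return kind, u, v
        pick -= c
    raise AssertionError("unreachable")


def _calibrate_temperature(
    scorer: Scorer, blocked, config: SAConfig, rng, n_proposals: int = 1000
) -> float:
    """Random-walk warm-up; T0 set so the median worsening move has
    acceptance probability 1/2."""
    state = _SAState(scorer, blocked, config.max_parents)
    worsening = []
    for _ in range(n_proposals):
        move = _propose(state, rng)
        if move is None:
            break
        kind, u, v = move
        delta, updates = state.delta(kind, u, v)
        if delta < 0:
            worsening.append(-delta)
        state.apply(kind, u, v, updates)
    if not worsening:
        return 1.0
    return float(np.median(worsening) / math.log(2.0))


def sa_search(
    data: DiscreteDataset,
    blocklist: EdgeBlocklist | None = None,
    config: SAConfig | None = None,
) -> DAGNetwork:
    """Simulated-annealing search for the highest-BDeu-scoring DAG.

    Returns the best-scoring network visited across all restarts.  If every
    move from the initial empty graph is blocked, the empty graph is
    returned with a warning.
    """
    config = config if config is not None else SAConfig()
    nodes = data.columns
    if len(nodes) < 2:
        raise ValidationError("need at least 2 variables to learn a network")
    scorer = Scorer(data, config.equivalent_sample_size)
    blocked = _blocked_matrix(nodes, blocklist)
    seeds = np.random.SeedSequence(config.seed).spawn(max(1, config.restarts))
    best_edges: set[tuple[str, str]] | None = None
    best_score = -math.inf
    trajectory: list[float] = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        t0 = config.initial_temperature
        if t0 is None:
            t0 = _calibrate_temperature(scorer, blocked, config, rng)
        state = _SAState(scorer, blocked, config.max_parents)
        if config.random_init:
            _random_init(state, rng)
        run_best_edges = state.edge_names()
        run_best = state.score
        temp = max(t0, 1e-12)
        start = time.monotonic()
        it = 0
        while True:
            if config.max_iterations is not None and it >= config.max_iterations:
                break
            if (
                config.time_budget is not None
                and time.monotonic() - start > config.time_budget
            ):
                break
            move = _propose(state, rng)
            if move is None:
                logger.warning(
                    "no legal move available; returning current graph"
                )
                break
            kind, u, v = move
            delta, updates = state.delta(kind, u, v)
            if delta >= 0 or rng.random() < math.exp(delta / temp):
                state.apply(kind, u, v, updates)
                if state.score > run_best + _TIE_TOL:
                    run_best = state.score
                    run_best_edges = state.edge_names()
            it += 1
            if it % config.moves_per_temperature == 0:
                temp = max(temp * config.cooling_factor, 1e-12)
        trajectory.append(run_best)
        better = run_best > best_score + _TIE_TOL
        tie = abs(run_best - best_score) <= _TIE_TOL and best_edges is not None
        if better or (tie and len(run_best_edges) < len(best_edges)):
            best_score = run_best
            best_edges = run_best_edges
    assert best_edges is not None
    arity = data.arity
    net = DAGNetwork(
        nodes=list(nodes),
        arities={c: int(arity[c]) for c in nodes},
        edges=best_edges,
        score=best_score,
    )
    return net


def network_score(
    network: DAGNetwork, data: DiscreteDataset, ess: float = 1.0
) -> float:
    """Recompute a network's total BDeu score from scratch."""
    return sum(
        bde_local_score(node, network.parents(node), data, ess)
        for node in network.nodes
    )


def learn_subset_networks(
    datasets: list[DiscreteDataset],
    blocklist: EdgeBlocklist | None,
    config: SAConfig,
) -> list[DAGNetwork]:
    """One top network per SNP subset, seeds derived from the master seed."""
    seeds = np.random.SeedSequence(config.seed).spawn(len(datasets))
    networks = []
    for i, (ds, seq) in enumerate(zip(datasets, seeds)):
        sub_config = replace(config, seed=int(seq.generate_state(1)[0] % 2**31))
        try:
            net = sa_search(ds, blocklist, sub_config)
        except Exception as exc:
            raise RuntimeError(f"structure search failed on subset {i}: {exc}") from exc
        logger.info(
            "subset %d: %d nodes, %d edges, score %.3f",
            i, len(net.nodes), len(net.edges), net.score,
        )
        networks.append(net)
    return networks
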