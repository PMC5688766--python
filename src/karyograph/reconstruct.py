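"""Karyotype reconstruction as an exact mixed-integer program on the bridge graph.

The reconstruction seeks nonnegative integer traversal counts for every
directed edge such that at every non-telomeric vertex each interval-edge
arrival is matched by a reference/bridge departure and vice versa (the valid
alternating-path constraints; telomeres are unconstrained), minimizing the
discordance score

    d_G(P) = sum_{e in E_I} (l_e / L) |f(e) - w(e)|
           + alpha * sum_{e in E_V} (w(e) / mu) (1 - min(1, f(e)))

where f(e) is the total traversal count of connection e, w(e) the observed CN
(interval edges) or support (bridge edges), l_e the interval length, L the
total genome length and mu the total bridge support.  The optimum is then
decomposed into telomere-to-telomere alternating paths -- the reconstructed
chromosomes -- plus any telomere-detached alternating cycles, which are
reported separately.

Public face, statsmodels-style::

    model = KaryotypeModel(segmentation, observed)   # or .from_files(...)
    res = model.fit(alpha=0.1)
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph import (
    BRIDGE,
    BridgeGraph,
    Connection,
    INTERVAL,
    REFERENCE,
    build_bridge_graph,
    connected_components,
)
from .segments import (
    Extremity,
    Karyotype,
    KaryographError,
    ObservedData,
    ReferenceSegmentation,
    SignedUnit,
    canonical_pair,
)

_FWD, _REV = 0, 1


class SolverError(KaryographError):
    """The MIP backend failed to return a proven-optimal solution."""


@dataclass
class EdgeMultiplicities:
    """Integer traversal counts per directed edge; ``f(e)`` is the per-connection
    total x_forward + x_reverse."""

    counts: dict[Connection, tuple[int, int]]

    def f(self, conn: Connection) -> int:
        x = self.counts.get(conn, (0, 0))
        return x[0] + x[1]

    def directed(self, conn: Connection, direction: int) -> int:
        return self.counts.get(conn, (0, 0))[direction]

    def items(self):
        return self.counts.items()


@dataclass
class Solution:
    """An optimal traversal-count assignment with its path decomposition."""

    multiplicities: EdgeMultiplicities
    paths: list[list[SignedUnit]]
    cycles: list[list[SignedUnit]]
    score: float
    alpha: float
    warnings: list[str] = field(default_factory=list)
    solver_status: str = "optimal"
    #: non-interval connections consumed as a walk's dangling first/last edge
    #: (the MIP leaves telomeres unconstrained, so such flows are feasible)
    stray_junctions: list[Connection] = field(default_factory=list)

    @property
    def karyotype(self) -> Karyotype:
        """The reconstructed karyotype (the telomere-to-telomere paths)."""
        return Karyotype([list(p) for p in self.paths])


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _as_f(f) -> "Mapping[Connection, int] | EdgeMultiplicities":
    return f


def discordance_score(g: BridgeGraph, f, alpha: float) -> float:
    """Evaluate d_G for traversal totals ``f`` (an EdgeMultiplicities or a
    mapping connection -> total count)."""
    get = f.f if isinstance(f, EdgeMultiplicities) else lambda c: f.get(c, 0)
    L = g.total_length
    mu = g.total_support
    score = 0.0
    for c in g.connections:
        fc = get(c)
        if fc < 0:
            raise KaryographError(f"negative traversal count for {c}")
        if c.kind == INTERVAL:
            score += g.interval_length(c) / L * abs(fc - c.weight)
        elif c.kind == BRIDGE and mu > 0:
            score += alpha * (c.weight / mu) * (1.0 - min(1.0, fc))
    return score


# ---------------------------------------------------------------------------
# The MIP
# ---------------------------------------------------------------------------

def _directed_incidence(c: Connection, v: Extremity) -> tuple[list[int], list[int]]:
    """Directions of ``c`` leaving / entering ``v`` (self-loops do both)."""
    if c.is_self_loop:
        if c.u == v:
            return [_FWD, _REV], [_FWD, _REV]
        return [], []
    leaving, entering = [], []
    if c.u == v:
        leaving.append(_FWD)
        entering.append(_REV)
    elif c.v == v:
        leaving.append(_REV)
        entering.append(_FWD)
    return leaving, entering


def formulate_and_solve(
    g: BridgeGraph,
    alpha: float,
    upper_bound: int | None = None,
    time_limit: float | None = None,
) -> EdgeMultiplicities:
    """Solve the reconstruction MIP to proven optimality (zero gap).

    The |f - w| terms are linearized with one continuous slack per interval
    connection; min(1, f) with one binary y <= f per bridge connection (the
    objective only rewards y = 1, so binaries suffice).  Variables are bounded
    by ceil(max CN weight) + #bridges + 2, which cannot cut off the optimum at
    realistic weights; the bound is configurable.
    """
    if alpha < 0:
        raise KaryographError("alpha must be >= 0")
    conns = g.connections
    n = len(conns)
    intervals = [k for k, c in enumerate(conns) if c.kind == INTERVAL]
    bridges = [k for k, c in enumerate(conns) if c.kind == BRIDGE]
    mu = g.total_support
    L = g.total_length

    if upper_bound is None:
        max_w = max((c.weight for c in conns if c.kind == INTERVAL), default=0.0)
        upper_bound = int(math.ceil(max(max_w, 0.0))) + len(bridges) + 2

    # variable layout: [x_fwd/x_rev per connection] [t per interval] [y per bridge]
    nx_ = 2 * n
    t_of = {k: nx_ + i for i, k in enumerate(intervals)}
    y_of = {k: nx_ + len(intervals) + i for i, k in enumerate(bridges)}
    nvar = nx_ + len(intervals) + len(bridges)

    obj = np.zeros(nvar)
    for k in intervals:
        obj[t_of[k]] = g.interval_length(conns[k]) / L
    for k in bridges:
        if mu > 0:
            obj[y_of[k]] = -alpha * conns[k].weight / mu

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lb: list[float] = []
    ub: list[float] = []
    nrow = 0

    def add(entries: Iterable[tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal nrow
        for col, val in entries:
            rows.append(nrow)
            cols.append(col)
            vals.append(val)
        lb.append(lo)
        ub.append(hi)
        nrow += 1

    # valid alternating-path (flow balance) constraints at non-telomeric vertices
    kidx = {c: k for k, c in enumerate(conns)}
    for v in g.vertices:
        if v in g.telomeres:
            continue
        ic = g.interval_at(v)
        ki = kidx[ic]
        i_leave, i_enter = _directed_incidence(ic, v)
        for interval_dirs, non_interval_pick in (
            (i_leave, "enter"),  # interval departures = non-interval arrivals
            (i_enter, "leave"),  # interval arrivals  = non-interval departures
        ):
            entries = [(2 * ki + d, 1.0) for d in interval_dirs]
            for c2 in g.non_interval_at(v):
                k2 = kidx[c2]
                leave, enter = _directed_incidence(c2, v)
                for d in leave if non_interval_pick == "leave" else enter:
                    entries.append((2 * k2 + d, -1.0))
            add(entries, 0.0, 0.0)

    # |f - w| linearization for interval connections
    for k in intervals:
        w = conns[k].weight
        t = t_of[k]
        add([(t, 1.0), (2 * k, -1.0), (2 * k + 1, -1.0)], -w, np.inf)
        add([(t, 1.0), (2 * k, 1.0), (2 * k + 1, 1.0)], w, np.inf)

    # y <= f for bridge connections
    for k in bridges:
        add([(2 * k, 1.0), (2 * k + 1, 1.0), (y_of[k], -1.0)], 0.0, np.inf)

    A = sparse.csc_array(
        (vals, (rows, cols)), shape=(nrow, nvar)
    ) if nrow else sparse.csc_array((0, nvar))

    lower = np.zeros(nvar)
    upper = np.empty(nvar)
    upper[:nx_] = upper_bound
    upper[nx_ : nx_ + len(intervals)] = np.inf
    upper[nx_ + len(intervals) :] = 1.0
    integrality = np.ones(nvar)
    integrality[nx_ : nx_ + len(intervals)] = 0.0  # slacks stay continuous

    options: dict = {"mip_rel_gap": 0.0}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c=obj,
        constraints=LinearConstraint(A, np.array(lb), np.array(ub)),
        integrality=integrality,
        bounds=Bounds(lower, upper),
        options=options,
    )
    if res.status == 1:
        raise SolverError(
            "MIP time limit reached before proven optimality"
            + (" (incumbent available)" if res.x is not None else "")
        )
    if res.status != 0 or res.x is None:
        raise SolverError(f"MIP solve failed: {res.message}")

    x = np.rint(res.x[:nx_]).astype(int)
    em = EdgeMultiplicities(
        {c: (int(x[2 * k]), int(x[2 * k + 1])) for k, c in enumerate(conns)}
    )
    assert_flow_balance(g, em)
    return em


def assert_flow_balance(g: BridgeGraph, em: EdgeMultiplicities) -> None:
    """Raise unless the alternating-path balance holds at every non-telomeric vertex."""
    for v in g.vertices:
        if v in g.telomeres:
            continue
        ic = g.interval_at(v)
        i_leave, i_enter = _directed_incidence(ic, v)
        ni_enter = ni_leave = 0
        for c2 in g.non_interval_at(v):
            leave, enter = _directed_incidence(c2, v)
            ni_leave += sum(em.directed(c2, d) for d in leave)
            ni_enter += sum(em.directed(c2, d) for d in enter)
        if sum(em.directed(ic, d) for d in i_leave) != ni_enter or sum(
            em.directed(ic, d) for d in i_enter
        ) != ni_leave:
            raise KaryographError(f"flow balance violated at {v}")


# ---------------------------------------------------------------------------
# Alternating path decomposition
# ---------------------------------------------------------------------------

def _conn_sort_key(c: Connection, d: int) -> tuple:
    return (0 if c.kind == REFERENCE else 1, c.u, c.v, d)


def decompose_paths(
    g: BridgeGraph, em: EdgeMultiplicities, alpha: float = 0.1
) -> Solution:
    """Hierholzer-style extraction of alternating walks from the optimum.

    At every telomere the directed totals determine exactly how many walks
    start there with an interval edge (si), start with a dangling non-interval
    edge (sn), end after an interval edge (ei), end with a dangling
    non-interval edge (en), and pass through in either phase (p1: interval in /
    non-interval out, p2: the reverse); passes are maximized so walks are as
    long as possible.  Dangling edges arise because the MIP leaves telomeres
    unconstrained; they are recorded as stray junctions with a warning.
    Leftover balanced capacity is extracted as alternating cycles, spliced into
    paths wherever a pre-interval vertex is shared; only genuinely detached
    cycles are reported separately.  Per-connection usage of paths + cycles +
    strays equals f(e) exactly (checked).
    """
    assert_flow_balance(g, em)
    cap: dict[tuple[Connection, int], int] = {}
    for c, (xf, xr) in em.items():
        cap[(c, _FWD)] = xf
        cap[(c, _REV)] = xr
    warnings: list[str] = []
    strays: list[Connection] = []

    si: dict[Extremity, int] = {}
    sn: dict[Extremity, int] = {}
    ei: dict[Extremity, int] = {}
    en: dict[Extremity, int] = {}
    p1: dict[Extremity, int] = {}
    p2: dict[Extremity, int] = {}
    for s in g.telomeres:
        ic = g.interval_at(s)
        il, ie = _directed_incidence(ic, s)
        i_leave = sum(em.directed(ic, d) for d in il)
        i_in = sum(em.directed(ic, d) for d in ie)
        ni_leave = ni_in = 0
        for c2 in g.non_interval_at(s):
            leave, enter = _directed_incidence(c2, s)
            ni_leave += sum(em.directed(c2, d) for d in leave)
            ni_in += sum(em.directed(c2, d) for d in enter)
        p1[s] = min(i_in, ni_leave)
        ei[s] = i_in - p1[s]
        sn[s] = ni_leave - p1[s]
        p2[s] = min(ni_in, i_leave)
        en[s] = ni_in - p2[s]
        si[s] = i_leave - p2[s]
        if sn[s] or en[s]:
            warnings.append(
                f"flow dangles on a non-interval edge at telomere {s} "
                f"(the MIP does not constrain telomeres)"
            )

    def take_interval(v: Extremity) -> tuple[SignedUnit, Extremity] | None:
        c = g.interval_at(v)
        d = _FWD if c.u == v else _REV
        if cap[(c, d)] == 0:
            return None
        cap[(c, d)] -= 1
        unit = (c.u.chrom, c.u.index, 1 if d == _FWD else -1)
        return unit, c.other(v) if not c.is_self_loop else v

    def non_interval_options(v: Extremity) -> list[tuple[Connection, int]]:
        opts = []
        for c2 in g.non_interval_at(v):
            if c2.is_self_loop:
                for d in (_FWD, _REV):
                    if cap[(c2, d)] > 0:
                        opts.append((c2, d))
            else:
                d = _FWD if c2.u == v else _REV
                if cap[(c2, d)] > 0:
                    opts.append((c2, d))
        opts.sort(key=lambda cd: _conn_sort_key(*cd))
        return opts

    def ni_dest(c2: Connection, d: int, v: Extremity) -> Extremity:
        return v if c2.is_self_loop else (c2.v if d == _FWD else c2.u)

    def walk(v0: Extremity, kind: str) -> list[SignedUnit]:
        """kind: 'path_i' (interval-first start), 'path_n' (non-interval-first
        start) or 'cycle'.  Consumes capacity and telomere event counters."""
        parts: list[SignedUnit] = []
        v = v0
        last_ni: Connection | None = None
        via_ni = False
        if kind == "path_n":
            opts = non_interval_options(v)
            if not opts:
                warnings.append(f"missing non-interval start capacity at {v}")
                return parts
            c2, d = opts[0]
            cap[(c2, d)] -= 1
            strays.append(c2)  # dangling first edge: no preceding interval unit
            v = ni_dest(c2, d, v)
            via_ni = True
        while True:
            if via_ni and v in g.telomeres:
                if p2.get(v, 0) > 0:
                    p2[v] -= 1  # pass through: continue with the interval edge
                else:
                    if en.get(v, 0) > 0:
                        en[v] -= 1
                    else:
                        warnings.append(f"unplanned walk end at telomere {v}")
                    if last_ni is not None:
                        strays.append(last_ni)  # dangling last edge
                    return parts
            step = take_interval(v)
            if step is None:
                if kind == "cycle" and v == v0 and via_ni:
                    return parts  # cycle closed at its origin
                warnings.append(f"walk stuck before interval step at {v}")
                if last_ni is not None:
                    strays.append(last_ni)
                return parts
            unit, v = step
            parts.append(unit)
            via_ni = False
            if v in g.telomeres:
                if p1.get(v, 0) > 0:
                    p1[v] -= 1  # pass through: continue with a non-interval edge
                elif kind != "cycle" and ei.get(v, 0) > 0:
                    ei[v] -= 1
                    return parts
                elif kind != "cycle":
                    warnings.append(f"unplanned interval-edge walk end at {v}")
                    return parts
                # cycles with p1 exhausted fall through and close via capacity
            opts = non_interval_options(v)
            if not opts:
                if kind != "cycle" or v != v0:
                    warnings.append(f"walk ended without a non-interval edge at {v}")
                return parts
            c2, d = opts[0]
            cap[(c2, d)] -= 1
            last_ni = c2
            v = ni_dest(c2, d, v)
            via_ni = True

    paths: list[list[SignedUnit]] = []
    for s in sorted(g.telomeres):
        while si[s] > 0:
            si[s] -= 1
            parts = walk(s, "path_i")
            if parts:
                paths.append(parts)
        while sn[s] > 0:
            sn[s] -= 1
            parts = walk(s, "path_n")
            if parts:
                paths.append(parts)

    cycles: list[list[SignedUnit]] = []
    while True:
        origin = None
        for v in sorted(g.vertices):
            c = g.interval_at(v)
            d = _FWD if c.u == v else _REV
            if cap[(c, d)] > 0:
                origin = v
                break
        if origin is None:
            break
        parts = walk(origin, "cycle")
        if not parts:
            break
        cycles.append(parts)

    leftover = sum(cap.values())
    if leftover:
        raise KaryographError(
            f"path decomposition left {leftover} directed traversals unconsumed"
        )

    paths, cycles = _splice_cycles(paths, cycles)
    if cycles:
        warnings.append(
            f"{len(cycles)} telomere-detached alternating cycle(s) in the optimum; "
            "reported separately from the path karyotype"
        )

    score = discordance_score(g, em, alpha)
    sol = Solution(em, paths, cycles, score, alpha, warnings, stray_junctions=strays)
    check_usage_conservation(g, em, sol)
    return sol


def _try_splice(host: list[SignedUnit], cyc: list[SignedUnit]) -> list[SignedUnit] | None:
    """Insert a closed alternating walk into ``host`` at a shared pre-interval
    vertex, rotating the cycle to start there.  The junction between two
    extremities is a unique connection, so the insertion re-uses exactly the
    junctions both walks already consumed -- per-connection usage is unchanged.
    """
    host_pos: dict[Extremity, int] = {}
    for k, u in enumerate(host):
        host_pos.setdefault(Karyotype.in_extremity(u), k)
    # a closed alternating walk may be traversed in either orientation; its
    # junctions map to the same connections and the score depends only on
    # per-connection totals, so both orientations are tried
    for oriented in (cyc, [(c, i, -s) for (c, i, s) in reversed(cyc)]):
        for r, u in enumerate(oriented):
            k = host_pos.get(Karyotype.in_extremity(u))
            if k is not None:
                return host[:k] + oriented[r:] + oriented[:r] + host[k:]
    return None


def _splice_cycles(
    paths: list[list[SignedUnit]], cycles: list[list[SignedUnit]]
) -> tuple[list[list[SignedUnit]], list[list[SignedUnit]]]:
    """Hierholzer splicing: absorb cycles into paths (or merge cycles) wherever
    they share a pre-interval vertex; only genuinely detached cycles remain."""
    pending = list(cycles)
    changed = True
    while changed and pending:
        changed = False
        for i, cyc in enumerate(pending):
            for j, host in enumerate(paths):
                merged = _try_splice(host, cyc)
                if merged is not None:
                    paths[j] = merged
                    del pending[i]
                    changed = True
                    break
            else:
                for j, host in enumerate(pending):
                    if j == i:
                        continue
                    merged = _try_splice(host, cyc)
                    if merged is not None:
                        pending[j] = merged
                        del pending[i]
                        changed = True
                        break
            if changed:
                break
    return paths, pending


def check_usage_conservation(
    g: BridgeGraph, em: EdgeMultiplicities, sol: Solution
) -> None:
    """Raise unless the decomposition's per-connection usage equals f(e).

    Interval usage is counted from the units of every path and cycle; junction
    usage from consecutive unit pairs, each cycle's closing junction, and the
    recorded stray (dangling) junctions.
    """
    interval_conn = {(c.u.chrom, c.u.index): c for c in g.interval_connections()}
    pair_conn = {
        canonical_pair(c.u, c.v): c for c in g.connections if c.kind != INTERVAL
    }
    used: dict[Connection, int] = {c: 0 for c in g.connections}
    for c in sol.stray_junctions:
        used[c] += 1

    def junction(u: SignedUnit, v: SignedUnit) -> None:
        a = Karyotype.out_extremity(u)
        b = Karyotype.in_extremity(v)
        c = pair_conn.get(canonical_pair(a, b))
        if c is None:
            raise KaryographError(f"decomposition uses unknown junction {a} -- {b}")
        used[c] += 1

    for walk_units, closed in [(p, False) for p in sol.paths] + [
        (c, True) for c in sol.cycles
    ]:
        for unit in walk_units:
            conn = interval_conn[(unit[0], unit[1])]
            used[conn] += 1
        for u, v in zip(walk_units, walk_units[1:]):
            junction(u, v)
        if closed and walk_units:
            junction(walk_units[-1], walk_units[0])

    for c in g.connections:
        if used[c] != em.f(c):
            raise KaryographError(
                f"decomposition uses {c} {used[c]} times, expected f = {em.f(c)}"
            )


# ---------------------------------------------------------------------------
# Traversal counts of an explicit karyotype (e.g. the simulated truth)
# ---------------------------------------------------------------------------

def karyotype_multiplicities(
    g: BridgeGraph, karyotype: Karyotype, on_missing: str = "error"
) -> EdgeMultiplicities:
    """Thread a karyotype through the graph and count directed-edge traversals.

    ``on_missing="skip"`` ignores junctions with no corresponding connection in
    the graph (e.g. a true bridge that went unobserved), which is how the true
    karyotype is scored against a noisy graph.
    """
    interval_conn = {
        (c.u.chrom, c.u.index): c for c in g.interval_connections()
    }
    pair_conn: dict[tuple[Extremity, Extremity], Connection] = {}
    for c in g.connections:
        if c.kind != INTERVAL:
            pair_conn[canonical_pair(c.u, c.v)] = c

    counts: dict[Connection, list[int]] = {c: [0, 0] for c in g.connections}
    for chrom in karyotype.chromosomes:
        for (cn, idx, s) in chrom:
            c = interval_conn.get((cn, idx))
            if c is None:
                raise KaryographError(f"karyotype references unknown interval {cn}:{idx}")
            counts[c][_FWD if s > 0 else _REV] += 1
        for u, v in zip(chrom, chrom[1:]):
            a = Karyotype.out_extremity(u)
            b = Karyotype.in_extremity(v)
            c = pair_conn.get(canonical_pair(a, b))
            if c is None:
                if on_missing == "skip":
                    continue
                raise KaryographError(f"no connection for junction {a} -- {b}")
            counts[c][_FWD if c.u == a else _REV] += 1
    return EdgeMultiplicities({c: (n[0], n[1]) for c, n in counts.items()})


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class KaryotypeModel:
    """Karyotype reconstruction model for one tumor sample.

    Parameters
    ----------
    segmentation : ReferenceSegmentation
        The reference chromosomes partitioned at the observed breakpoints.
    observed : ObservedData
        Real-valued CN per interval plus bridges with support.
    """

    def __init__(self, segmentation: ReferenceSegmentation, observed: ObservedData):
        observed.validate_against(segmentation)
        self.segmentation = segmentation
        self.observed = observed
        self.graph = build_bridge_graph(segmentation, observed)

    @classmethod
    def from_files(cls, cn_path, bridges_path) -> "KaryotypeModel":
        from .fileio import read_observed

        seg, obs = read_observed(cn_path, bridges_path)
        return cls(seg, obs)

    def fit(
        self,
        alpha: float = 0.1,
        split_components: bool = True,
        upper_bound: int | None = None,
        time_limit: float | None = None,
    ) -> "KaryotypeResults":
        """Solve the MIP (optionally per connected component -- exactly
        equivalent, since the objective separates over components under the
        shared normalizers L and mu) and decompose the optimum into paths."""
        if split_components:
            merged: dict[Connection, tuple[int, int]] = {}
            for comp in connected_components(self.graph):
                em = formulate_and_solve(
                    comp, alpha, upper_bound=upper_bound, time_limit=time_limit
                )
                merged.update(em.counts)
            em = EdgeMultiplicities(merged)
        else:
            em = formulate_and_solve(
                self.graph, alpha, upper_bound=upper_bound, time_limit=time_limit
            )
        solution = decompose_paths(self.graph, em, alpha)
        return KaryotypeResults(self, solution)


class KaryotypeResults:
    """Fitted reconstruction: optimal traversal counts, the decomposed
    karyotype, the discordance score and per-interval diagnostics."""

    def __init__(self, model: KaryotypeModel, solution: Solution):
        self.model = model
        self.solution = solution

    # -- convenience accessors --------------------------------------------
    @property
    def score(self) -> float:
        return self.solution.score

    @property
    def alpha(self) -> float:
        return self.solution.alpha

    @property
    def multiplicities(self) -> EdgeMultiplicities:
        return self.solution.multiplicities

    @property
    def paths(self) -> list[list[SignedUnit]]:
        return self.solution.paths

    @property
    def cycles(self) -> list[list[SignedUnit]]:
        return self.solution.cycles

    @property
    def karyotype(self) -> Karyotype:
        return self.solution.karyotype

    @property
    def cn_fitted(self) -> dict[tuple[str, int], int]:
        """Reconstructed integer CN per interval (= f on its interval edge)."""
        em = self.solution.multiplicities
        return {
            (c.u.chrom, c.u.index): em.f(c)
            for c in self.model.graph.interval_connections()
        }

    @property
    def bridges_used(self) -> set[tuple[Extremity, Extremity]]:
        em = self.solution.multiplicities
        return {
            canonical_pair(c.u, c.v)
            for c in self.model.graph.bridge_connections()
            if em.f(c) >= 1
        }

    def summary(self) -> str:
        g = self.model.graph
        em = self.solution.multiplicities
        lines = [
            "Karyotype reconstruction results",
            "=" * 64,
            f"intervals: {g.segmentation.n_intervals}   bridges: "
            f"{len(g.bridge_connections())}   L: {g.total_length:g}   "
            f"mu: {g.total_support:g}",
            f"alpha: {self.alpha:g}   discordance score: {self.score:.6f}",
            f"paths: {len(self.paths)}   detached cycles: {len(self.cycles)}",
            "-" * 64,
            f"{'interval':>12} {'length':>7} {'CN obs':>8} {'CN fit':>7} {'|diff|':>7}",
        ]
        for c in g.interval_connections():
            key = f"{c.u.chrom}:{c.u.index}"
            lines.append(
                f"{key:>12} {g.interval_length(c):>7d} {c.weight:>8.3f} "
                f"{em.f(c):>7d} {abs(em.f(c) - c.weight):>7.3f}"
            )
        if g.bridge_connections():
            lines.append("-" * 64)
            lines.append(f"{'bridge':>28} {'support':>8} {'used (f)':>9}")
            for c in g.bridge_connections():
                lines.append(f"{f'{c.u} -- {c.v}':>28} {c.weight:>8.3f} {em.f(c):>9d}")
        for w in self.solution.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_dot(self) -> str:
        from .viz import to_dot

        return to_dot(self.model.graph, self.solution)

    def save(self, out_dir) -> None:
        from .fileio import write_solution

        write_solution(self.solution, out_dir)
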