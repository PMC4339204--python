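"""Deformable fit of the cranial surface to edge candidates.

The fit minimises a single energy over three groups of unknowns: the
discrete assignment ``q`` of one edge candidate to each surface point,
the continuous surface coordinates ``U`` of those points, and the
control vertices ``X``::

    E(q, U, X) = sum_i [ ||c_qi - M(u_i, X)||^2
                         + lam1 ||phi_qi - Mphi(u_i, X)||^2 ]
                 + lam2 * sum_{(i,j) in N} ||c_qi - c_qj||^2
                 + lam3 * sum_i ||x_i - x_i^0||^2
                 + lam4 * sum_{(i,j) in T} ||x_i - x_j||^2

i.e. a position+orientation unary data term, a pairwise term keeping
neighbouring points on spatially coherent candidates, an anchor to the
initial placement X0, and a control-mesh smoothness regulariser.  All
energies are in mm^2; candidate positions are world mm.

Minimisation alternates a discrete step (choose q with U, X fixed;
max-product belief propagation on a spanning tree of the neighbour
graph, polished by iterated conditional modes, with exact enumeration
on tiny instances) and a continuous step (joint Levenberg-Marquardt-
style nonlinear least squares over X and U with q fixed).  Each
half-step never increases the energy, so the energy trace is
monotonically non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .edges import EdgeCandidateSet
from .surface import Surface, SurfaceSampling

EXACT_ENUMERATION_LIMIT = 4096


@dataclass
class EnergyParams:
    """Weights of the fitting energy; all non-negative, dimensionless."""

    lam1: float = 1.0    # orientation mismatch inside the unary term
    lam2: float = 0.1    # pairwise candidate coherence
    lam3: float = 0.01   # anchor to the initial placement
    lam4: float = 0.1    # control-mesh smoothness

    def __post_init__(self):
        if min(self.lam1, self.lam2, self.lam3, self.lam4) < 0:
            raise ValueError("energy weights must be non-negative")


@dataclass
class EnergyBreakdown:
    unary: float
    pairwise: float
    user: float
    reg: float
    lam2: float
    lam3: float
    lam4: float

    @property
    def total(self) -> float:
        return (self.unary + self.lam2 * self.pairwise
                + self.lam3 * self.user + self.lam4 * self.reg)


def energy(surface: Surface, sampling: SurfaceSampling, q: np.ndarray,
           X: np.ndarray, X0: np.ndarray, candidates: EdgeCandidateSet,
           params: EnergyParams) -> EnergyBreakdown:
    """Evaluate the full energy; ``q`` entries of -1 mark surface points
    without a candidate (their unary term is dropped -- occlusion
    tolerance)."""
    q = np.asarray(q, dtype=int)
    if len(q) != len(sampling):
        raise ValueError("q must assign every surface point")
    active = q >= 0
    if np.any(q[active] >= len(candidates)):
        raise IndexError("candidate index out of range")
    pts, nrm = surface.evaluate(sampling.face_ids, sampling.st, X)
    unary = 0.0
    if np.any(active):
        c = candidates.positions[q[active]]
        phi = candidates.normals[q[active]]
        unary = float(np.sum((c - pts[active]) ** 2)
                      + params.lam1 * np.sum((phi - nrm[active]) ** 2))
    pw = 0.0
    for i, j in sampling.neighbour_graph:
        if q[i] >= 0 and q[j] >= 0:
            diff = candidates.positions[q[i]] - candidates.positions[q[j]]
            pw += float(diff @ diff)
    user = float(np.sum((X - X0) ** 2))
    e = surface.mesh.edge_set
    reg = float(np.sum((X[e[:, 0]] - X[e[:, 1]]) ** 2))
    return EnergyBreakdown(unary, pw, user, reg,
                           params.lam2, params.lam3, params.lam4)


# --------------------------------------------------------------------------
# candidate pruning
# --------------------------------------------------------------------------

def prune_candidates(points: np.ndarray, candidates: EdgeCandidateSet,
                     k: int = 10, radius: float = 15.0,
                     extra: np.ndarray | None = None) -> list[np.ndarray]:
    """Per surface point: indices of the k nearest candidates within
    ``radius`` mm.  ``extra`` (e.g. the previous assignment) is always
    kept in its point's list so earlier assignments stay reachable."""
    tree = cKDTree(candidates.positions)
    kk = min(k, len(candidates))
    dist, idx = tree.query(points, k=kk)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    lists = []
    for i in range(len(points)):
        sel = idx[i][dist[i] <= radius]
        if extra is not None and extra[i] >= 0 and extra[i] not in sel:
            sel = np.append(sel, extra[i])
        lists.append(np.asarray(sorted(set(int(s) for s in sel)), dtype=int))
    return lists


# --------------------------------------------------------------------------
# discrete step
# --------------------------------------------------------------------------

def _unary_costs(cand_lists, candidates, pts, nrm, lam1):
    out = []
    for i, lst in enumerate(cand_lists):
        if len(lst) == 0:
            out.append(np.empty(0))
            continue
        c = candidates.positions[lst]
        phi = candidates.normals[lst]
        out.append(np.sum((c - pts[i]) ** 2, axis=1)
                   + lam1 * np.sum((phi - nrm[i]) ** 2, axis=1))
    return out


def _assignment_energy(q_local, cand_lists, unary, edges_local, cpos, lam2):
    """Energy (unary + pairwise only) of a local assignment."""
    tot = 0.0
    for i, qi in enumerate(q_local):
        if qi >= 0:
            tot += unary[i][qi]
    for i, j in edges_local:
        qi, qj = q_local[i], q_local[j]
        if qi >= 0 and qj >= 0:
            d = cpos[cand_lists[i][qi]] - cpos[cand_lists[j][qj]]
            tot += lam2 * float(d @ d)
    return tot


def _icm(q_local, cand_lists, unary, adj, cpos, lam2, max_sweeps=50):
    """Iterated conditional modes on the full neighbour graph; energy is
    non-increasing per move, ties broken toward the lowest index."""
    q = list(q_local)
    n = len(q)
    for _ in range(max_sweeps):
        changed = False
        for i in range(n):
            lst = cand_lists[i]
            if len(lst) == 0:
                continue
            cost = unary[i].copy()
            for j in adj[i]:
                if q[j] >= 0:
                    d = cpos[lst] - cpos[cand_lists[j][q[j]]]
                    cost = cost + lam2 * np.sum(d * d, axis=1)
            best = int(np.argmin(cost))
            if best != q[i]:
                q[i] = best
                changed = True
        if not changed:
            break
    return q


def _spanning_forest(n, edges):
    """BFS spanning forest over the active-point neighbour graph;
    returns a parent array (-1 at roots) and a topological order."""
    adj = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    parent = np.full(n, -2, dtype=int)
    order = []
    for root in range(n):
        if parent[root] != -2:
            continue
        parent[root] = -1
        queue = [root]
        while queue:
            u = queue.pop(0)
            order.append(u)
            for v in adj[u]:
                if parent[v] == -2:
                    parent[v] = u
                    queue.append(v)
    return parent, order


def _bp_tree(cand_lists, unary, parent, order, cpos, lam2):
    """Exact min-sum dynamic programming on the spanning forest."""
    n = len(cand_lists)
    msg = [np.zeros(len(cand_lists[i])) for i in range(n)]
    argmin_tab: dict[int, np.ndarray] = {}
    cost = [unary[i] + 0.0 for i in range(n)]
    for u in reversed(order):
        p = parent[u]
        if p < 0:
            continue
        if len(cand_lists[u]) == 0 or len(cand_lists[p]) == 0:
            continue
        cu = cpos[cand_lists[u]]
        cp = cpos[cand_lists[p]]
        pair = lam2 * np.sum(
            (cu[:, None, :] - cp[None, :, :]) ** 2, axis=2)  # (ku, kp)
        tot = cost[u][:, None] + pair
        argmin_tab[u] = np.argmin(tot, axis=0)
        cost[p] = cost[p] + np.min(tot, axis=0)
    q = [-1] * n
    for u in order:
        if len(cand_lists[u]) == 0:
            continue
        p = parent[u]
        if p < 0 or len(cand_lists[p]) == 0:
            q[u] = int(np.argmin(cost[u]))
        else:
            q[u] = int(argmin_tab[u][q[p]])
    return q


def select_correspondences(surface: Surface, sampling: SurfaceSampling,
                           X: np.ndarray, candidates: EdgeCandidateSet,
                           params: EnergyParams,
                           cand_lists: list[np.ndarray] | None = None,
                           prev_q: np.ndarray | None = None,
                           prune_k: int = 10,
                           prune_radius: float = 15.0) -> np.ndarray:
    """Choose the candidate assignment q with (U, X) fixed.

    Tiny instances (joint state space <= EXACT_ENUMERATION_LIMIT) are
    solved by exhaustive enumeration; larger ones by belief propagation
    on a spanning tree of the neighbour graph followed by ICM.  The
    returned assignment never has higher energy than the independent
    per-point unary minimiser, nor than ``prev_q`` when given.  Points
    with no candidate in reach get q = -1 and are flagged by dropping
    their unary term.
    """
    pts, nrm = surface.evaluate(sampling.face_ids, sampling.st, X)
    if cand_lists is None:
        cand_lists = prune_candidates(pts, candidates, k=prune_k,
                                      radius=prune_radius, extra=prev_q)
    unary = _unary_costs(cand_lists, candidates, pts, nrm, params.lam1)
    n = len(sampling)
    cpos = candidates.positions
    edges_local = [(int(i), int(j)) for i, j in sampling.neighbour_graph
                   if len(cand_lists[i]) > 0 and len(cand_lists[j]) > 0]
    sizes = [len(l) for l in cand_lists]

    def to_global(q_local):
        return np.array([cand_lists[i][q_local[i]] if q_local[i] >= 0 else -1
                         for i in range(n)], dtype=int)

    state_count = 1.0
    for s in sizes:
        state_count *= max(s, 1)
        if state_count > EXACT_ENUMERATION_LIMIT:
            break
    if params.lam2 == 0 or all(s <= 1 for s in sizes):
        q_local = [int(np.argmin(unary[i])) if sizes[i] else -1
                   for i in range(n)]
        return to_global(q_local)

    if state_count <= EXACT_ENUMERATION_LIMIT:
        import itertools
        ranges = [range(s) if s else [-1] for s in sizes]
        best_q, best_e = None, math.inf
        for combo in itertools.product(*ranges):
            e = _assignment_energy(combo, cand_lists, unary, edges_local,
                                   cpos, params.lam2)
            if e < best_e - 1e-15:
                best_q, best_e = combo, e
        return to_global(list(best_q))

    adj = [[] for _ in range(n)]
    for i, j in edges_local:
        adj[i].append(j)
        adj[j].append(i)
    parent, order = _spanning_forest(n, edges_local)
    starts = []
    starts.append(_bp_tree(cand_lists, unary, parent, order, cpos,
                           params.lam2))
    starts.append([int(np.argmin(unary[i])) if sizes[i] else -1
                   for i in range(n)])
    if prev_q is not None:
        prev_local = []
        ok = True
        for i in range(n):
            if prev_q[i] < 0:
                prev_local.append(int(np.argmin(unary[i])) if sizes[i] else -1)
            else:
                loc = np.nonzero(cand_lists[i] == prev_q[i])[0]
                if len(loc) == 0:
                    ok = False
                    break
                prev_local.append(int(loc[0]))
        if ok:
            starts.append(prev_local)
    best_q, best_e = None, math.inf
    for s0 in starts:
        qq = _icm(s0, cand_lists, unary, adj, cpos, params.lam2)
        e = _assignment_energy(qq, cand_lists, unary, edges_local, cpos,
                               params.lam2)
        if e < best_e - 1e-12:
            best_q, best_e = qq, e
    return to_global(best_q)


# --------------------------------------------------------------------------
# continuous step
# --------------------------------------------------------------------------

def refine(surface: Surface, sampling: SurfaceSampling, q: np.ndarray,
           X: np.ndarray, X0: np.ndarray, candidates: EdgeCandidateSet,
           params: EnergyParams, max_nfev: int = 60,
           xtol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Joint nonlinear least squares over (X, U) with q fixed.

    Returns (st_new, X_new, improved).  Surface coordinates stay inside
    the unit square of their originating face (bound constraints); the
    pairwise term is constant in (X, U) and therefore omitted from the
    residuals.  If the solver fails to decrease the cost the inputs are
    returned unchanged with ``improved=False``.
    """
    q = np.asarray(q, int)
    active = np.nonzero(q >= 0)[0]
    nx = surface.mesh.n_vertices
    na = len(active)
    edges = surface.mesh.edge_set
    c_t = candidates.positions[q[active]] if na else np.zeros((0, 3))
    phi_t = candidates.normals[q[active]] if na else np.zeros((0, 3))
    sl1, sl3, sl4 = (math.sqrt(params.lam1), math.sqrt(params.lam3),
                     math.sqrt(params.lam4))
    face_ids_a = sampling.face_ids[active]

    def unpack(z):
        Xz = z[:3 * nx].reshape(nx, 3)
        stz = z[3 * nx:].reshape(na, 2)
        return Xz, stz

    def residuals(z):
        Xz, stz = unpack(z)
        res = []
        if na:
            p, nvec = surface.evaluate(face_ids_a, stz, Xz)
            res.append((c_t - p).ravel())
            res.append((sl1 * (phi_t - nvec)).ravel())
        res.append((sl3 * (Xz - X0)).ravel())
        res.append((sl4 * (Xz[edges[:, 0]] - Xz[edges[:, 1]])).ravel())
        return np.concatenate(res)

    z0 = np.concatenate([np.asarray(X, float).ravel(),
                         sampling.st[active].ravel()])
    lo = np.concatenate([np.full(3 * nx, -np.inf), np.zeros(2 * na)])
    hi = np.concatenate([np.full(3 * nx, np.inf), np.ones(2 * na)])

    # Jacobian sparsity: unary residuals touch the control vertices that
    # support their face plus their own two surface coordinates;
    # anchor/regulariser rows touch specific control vertices only.
    rows, cols = [], []
    r = 0
    if na:
        for k, i in enumerate(active):
            sup = surface.face_support(int(sampling.face_ids[i]))
            xcols = np.concatenate([3 * sup, 3 * sup + 1, 3 * sup + 2])
            ucols = 3 * nx + np.array([2 * k, 2 * k + 1])
            allc = np.concatenate([xcols, ucols])
            # position rows 3k..3k+2, normal rows 3*na+3k..3*na+3k+2
            for rr in (3 * k, 3 * k + 1, 3 * k + 2,
                       3 * na + 3 * k, 3 * na + 3 * k + 1,
                       3 * na + 3 * k + 2):
                rows.extend([rr] * len(allc))
                cols.extend(int(cc) for cc in allc)
        r = 6 * na
    for v in range(nx):
        for ax in range(3):
            rows.append(r + 3 * v + ax)
            cols.append(3 * v + ax)
    r += 3 * nx
    for ei, (i, j) in enumerate(edges):
        for ax in range(3):
            rows.append(r + 3 * ei + ax)
            cols.append(3 * int(i) + ax)
            rows.append(r + 3 * ei + ax)
            cols.append(3 * int(j) + ax)
    r += 3 * len(edges)
    spar = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                         shape=(r, len(z0))).tocsr()

    res0 = residuals(z0)
    cost0 = float(res0 @ res0)
    sol = least_squares(residuals, z0, bounds=(lo, hi), method="trf",
                        jac_sparsity=spar, max_nfev=max_nfev, xtol=xtol,
                        x_scale="jac")
    cost1 = float(sol.fun @ sol.fun)
    if not np.isfinite(cost1) or cost1 > cost0:
        return sampling.st.copy(), np.asarray(X, float).copy(), False
    Xn, stn = unpack(sol.x)
    st_full = sampling.st.copy()
    st_full[active] = np.clip(stn, 0.0, 1.0)
    return st_full, Xn, True


# --------------------------------------------------------------------------
# alternation
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    X_star: np.ndarray
    st_star: np.ndarray
    q_star: np.ndarray
    energy_trace: list[dict] = field(default_factory=list)
    converged: bool = False
    dropped_points: int = 0

    @property
    def totals(self) -> np.ndarray:
        return np.array([t["total"] for t in self.energy_trace])


def fit(candidates: EdgeCandidateSet, surface: Surface,
        sampling: SurfaceSampling, X0: np.ndarray,
        params: EnergyParams | None = None,
        max_alternations: int = 10, tol: float = 1e-4,
        prune_k: int = 10, prune_radius: float = 15.0) -> FitResult:
    """Alternate discrete correspondence selection and continuous
    refinement until the relative energy decrease falls below ``tol``.

    The energy trace records every half-step (stage 'select'/'refine')
    and is non-increasing throughout.
    """
    if params is None:
        params = EnergyParams()
    if len(candidates) == 0:
        raise ValueError("empty candidate set: no edges above the FA "
                         "threshold; lower the threshold and re-detect")
    X = np.asarray(X0, float).copy()
    X0 = np.asarray(X0, float).copy()
    samp = SurfaceSampling(sampling.face_ids.copy(), sampling.st.copy(),
                           sampling.neighbour_graph)
    trace: list[dict] = []
    q = None
    converged = False
    for it in range(max_alternations):
        pts, _ = surface.evaluate(samp.face_ids, samp.st, X)
        lists = prune_candidates(pts, candidates, k=prune_k,
                                 radius=prune_radius, extra=q)
        q = select_correspondences(surface, samp, X, candidates, params,
                                   cand_lists=lists, prev_q=q)
        eb = energy(surface, samp, q, X, X0, candidates, params)
        trace.append(dict(iteration=it, stage="select", total=eb.total,
                          unary=eb.unary, pairwise=eb.pairwise,
                          user=eb.user, reg=eb.reg))
        st_new, X_new, _ = refine(surface, samp, q, X, X0, candidates,
                                  params)
        samp = SurfaceSampling(samp.face_ids, st_new, samp.neighbour_graph)
        X = X_new
        eb = energy(surface, samp, q, X, X0, candidates, params)
        trace.append(dict(iteration=it, stage="refine", total=eb.total,
                          unary=eb.unary, pairwise=eb.pairwise,
                          user=eb.user, reg=eb.reg))
        if it > 0:
            prev = trace[-4]["total"]
            now = trace[-1]["total"]
            if prev > 0 and (prev - now) / prev < tol:
                converged = True
                break
    return FitResult(X_star=X, st_star=samp.st, q_star=q,
                     energy_trace=trace, converged=converged,
                     dropped_points=int(np.sum(q < 0)))


def fit_volume(volume: np.ndarray, spacing: float, surface: Surface,
               sampling: SurfaceSampling, X0: np.ndarray,
               params: EnergyParams | None = None,
               fa_threshold: float = 0.3, **kwargs) -> FitResult:
    """Detect candidates with feature asymmetry, then fit."""
    from .edges import detect_skull_candidates
    cands = detect_skull_candidates(volume, spacing, threshold=fa_threshold)
    if len(cands) == 0:
        raise ValueError(
            f"no edge candidates at FA threshold {fa_threshold}; "
            "lower the threshold")
    return fit(cands, surface, sampling, X0, params=params, **kwargs)
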