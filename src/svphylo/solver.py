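"""Coordinate-descent deconvolution: frequency LP (U-step) and phylogeny ILP (C-step).

The method minimizes ``|F - UC| + lambda1 * R + lambda2 * S`` over clone
profiles ``C`` (integer, allele-specific) and clone frequencies ``U`` (rows
on the simplex), where ``R`` is the total absolute allele-specific segment
copy change over tree edges (a minimum-evolution penalty) and ``S`` the
absolute mismatch between observed VAFs and the VAFs implied by ``(U, C)``.
The C-step is a mixed-integer program over the copy numbers, the binary tree
(edge matrix E, ancestry A), the variant-introduction tensor W (Dollo: one
gain per variant, losses only through allele copy loss) and the allele
assignment D; the U-step is a per-sample LP. Both are solved with HiGHS
through :mod:`scipy.optimize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model import (
    BulkObservation,
    CloneProfiles,
    CloneTree,
    FrequencyMatrix,
    VariantPanel,
)

__all__ = [
    "SolverConfig",
    "SolveResult",
    "default_lambdas",
    "solve_U_step",
    "solve_C_step",
    "coordinate_descent",
    "compute_objective",
    "collapse_tree",
    "CollapsedTree",
]


class SolverError(RuntimeError):
    pass


@dataclass
class SolverConfig:
    """Settings for one deconvolution run.

    ``n_leaves`` sets the tree size N = 2n - 1 (use ``from_max_nodes`` for the
    max-node-count mode in which the clone number is later estimated by
    collapsing). ``lambda1``/``lambda2`` default to scale-normalizing values
    computed from the instance dimensions. ``phasing`` selects how variant
    copy changes couple to allele segment copy changes on edges where the
    variant already exists: ``"strict"`` forces equal changes, ``"relaxed"``
    only bounds their magnitude by the segment change.
    """

    n_leaves: int = 2
    c_max: int = 10
    lambda1: float | None = None
    lambda2: float | None = None
    max_iters: int = 10
    time_limit_per_iter: float = 1000.0
    n_restarts: int = 5
    convergence_tol: float = 1e-4
    leaf_only: bool = False
    phasing: str = "strict"
    seed: int | None = None
    mip_gap: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise SolverError("n_leaves must be >= 2")
        if self.c_max < 1:
            raise SolverError("c_max must be >= 1")
        if self.phasing not in ("strict", "relaxed"):
            raise SolverError("phasing must be 'strict' or 'relaxed'")

    @classmethod
    def from_max_nodes(cls, max_nodes: int = 9, **kw) -> "SolverConfig":
        if max_nodes < 3 or max_nodes % 2 == 0:
            raise SolverError("max_nodes must be an odd integer >= 3")
        return cls(n_leaves=(max_nodes + 1) // 2, **kw)


@dataclass
class SolveResult:
    tree: CloneTree
    profiles: CloneProfiles
    freqs: FrequencyMatrix
    objective: float
    data_term: float
    R: float
    S: float
    trace: list[dict] = field(default_factory=list)
    optimal: bool = True
    restart_seeds: list[int] = field(default_factory=list)


def default_lambdas(l: int, g: int, r: int, m: int, N: int) -> tuple[float, float]:
    """Scale-normalizing regularization weights.

    lambda1 = (l+g+2r) / (2 * 2r * m * N) balances R against the data term
    (whose scale grows with the number of F entries); lambda2 =
    (l+g+2r) / (2 * (l+g)) balances the VAF-consistency term S.
    """
    if l + g <= 0:
        raise SolverError("lambda2 undefined: no breakpoints or SNVs (l + g = 0)")
    if r <= 0 or m <= 0 or N <= 0:
        raise SolverError("lambda1 undefined: counts must be positive")
    ncol = l + g + 2 * r
    lam1 = ncol / (2.0 * (2 * r * m * N))
    lam2 = ncol / (2.0 * (l + g))
    return lam1, lam2


# ---------------------------------------------------------------------------
# U-step: per-sample LP on the simplex
# ---------------------------------------------------------------------------

def solve_U_step(
    F: np.ndarray, C: np.ndarray, n_leaves: int, leaf_only: bool = False
) -> FrequencyMatrix:
    """Global optimum of sum |F - UC| over U >= 0 with unit row sums.

    Each sample is an independent LP: variables (u, t) with t >= +-(F_p - uC),
    minimizing sum t. In leaf-only mode internal non-root clones are fixed to
    frequency zero.
    """
    F = np.asarray(F, dtype=float)
    C = np.asarray(C, dtype=float)
    m, nc = F.shape
    N = C.shape[0]
    root = N - 1
    nvar = N + nc
    cost = np.concatenate([np.zeros(N), np.ones(nc)])
    # t_v >= F[p,v] - sum_k u_k C[k,v]   and   t_v >= sum_k u_k C[k,v] - F[p,v]
    I = sparse.eye(nc, format="csr")
    A_pos = sparse.hstack([sparse.csr_matrix(C.T), I])   # uC + t >= F
    A_neg = sparse.hstack([sparse.csr_matrix(C.T), -I])  # uC - t <= F
    A_eq = sparse.hstack([sparse.csr_matrix(np.ones((1, N))), sparse.csr_matrix((1, nc))])
    ub = np.ones(N + nc) * np.inf
    lb = np.zeros(N + nc)
    if leaf_only:
        for k in range(n_leaves, root):
            ub[k] = 0.0
    U = np.zeros((m, N))
    for p in range(m):
        A_ub = sparse.vstack([-A_pos, A_neg]).tocsc()
        b_ub = np.concatenate([-F[p], F[p]])  # -(uC + t) <= -F ; uC - t <= F
        res = linprog(
            cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
            bounds=np.column_stack([lb, ub]), method="highs",
        )
        if not res.success:
            raise SolverError(f"U-step LP failed for sample {p}: {res.message}")
        U[p] = res.x[:N]
    # clean tiny negatives from the interior-point/crossover path
    U = np.clip(U, 0.0, None)
    return FrequencyMatrix(U=U, leaf_only=leaf_only)


# ---------------------------------------------------------------------------
# C-step: MILP over profiles + tree
# ---------------------------------------------------------------------------

class _Rows:
    """Accumulates sparse constraint rows."""

    def __init__(self) -> None:
        self.data: list[float] = []
        self.ri: list[int] = []
        self.ci: list[int] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.n = 0

    def add(self, cols, coefs, lb=-np.inf, ub=np.inf) -> None:
        self.ri.extend([self.n] * len(cols))
        self.ci.extend(cols)
        self.data.extend(coefs)
        self.lb.append(lb)
        self.ub.append(ub)
        self.n += 1

    def matrix(self, nvar: int) -> sparse.csr_matrix:
        return sparse.coo_matrix(
            (self.data, (self.ri, self.ci)), shape=(self.n, nvar)
        ).tocsr()


class _CStepModel:
    """Index bookkeeping + constraint assembly for the C-step MILP."""

    def __init__(self, F, U, panel: VariantPanel, config: SolverConfig):
        self.F = np.asarray(F, dtype=float)
        self.U = np.asarray(U, dtype=float)
        self.panel = panel
        self.cfg = config
        self.m, self.nc = self.F.shape
        self.N = 2 * config.n_leaves - 1
        self.n = config.n_leaves
        self.V = panel.n_variants
        self.r = panel.r
        self.root = self.N - 1
        self.cmax = config.c_max
        if self.nc != panel.n_cols:
            raise SolverError(f"F has {self.nc} columns, panel expects {panel.n_cols}")
        self._alloc()

    # --- variable blocks -------------------------------------------------
    def _alloc(self) -> None:
        N, V, r, m, nc = self.N, self.V, self.r, self.m, self.nc
        o = 0

        def block(size):
            nonlocal o
            s = o
            o += size
            return s

        self.oC = block(N * nc)
        self.oCbar = block(N * V)
        self.oE = block(N * N)
        self.oA = block(N * N)
        self.oW = block(N * N * V)
        self.oX = block(2 * N * N * r)
        self.oT = block(m * nc)
        self.oZ = block(m * V)
        self.oD = block(V)
        self.nvar = o

    def iC(self, k, v):
        return self.oC + k * self.nc + v

    def iCbar(self, k, b):
        return self.oCbar + k * self.V + b

    def iE(self, i, j):
        return self.oE + i * self.N + j

    def iA(self, i, j):
        return self.oA + i * self.N + j

    def iW(self, i, j, b):
        return self.oW + (i * self.N + j) * self.V + b

    def iX(self, a, i, j, s):
        return self.oX + ((a * self.N + i) * self.N + j) * self.r + s

    def iT(self, p, v):
        return self.oT + p * self.nc + v

    def iZ(self, p, b):
        return self.oZ + p * self.V + b

    def iD(self, b):
        return self.oD + b

    def edge_pairs(self):
        """Candidate (parent, child) pairs: parents internal, children non-root.

        Internal children must have a higher-index parent (any tree can be
        relabeled to satisfy this, so it only removes symmetric relabelings
        of the internal nodes, not topologies).
        """
        for i in range(self.n, self.N):
            for j in range(self.N - 1):
                if i != j and (j < self.n or i > j):
                    yield i, j

    # --- bounds & integrality -------------------------------------------
    def bounds(self) -> Bounds:
        lb = np.zeros(self.nvar)
        ub = np.full(self.nvar, np.inf)
        N, V, nc, r = self.N, self.V, self.nc, self.r
        ub[self.oC : self.oC + N * nc] = self.cmax
        ub[self.oCbar : self.oCbar + N * V] = 1
        ub[self.oE : self.oE + N * N] = 0  # enable only candidate pairs below
        ub[self.oA : self.oA + N * N] = 1
        ub[self.oW : self.oW + N * N * V] = 0
        ub[self.oX : self.oX + 2 * N * N * r] = self.cmax
        ub[self.oD : self.oD + V] = 1
        for i, j in self.edge_pairs():
            ub[self.iE(i, j)] = 1
            for b in range(V):
                ub[self.iW(i, j, b)] = 1
        for i in range(N):
            ub[self.iA(i, i)] = 0
        # root row of C: variants 0, segments 1
        for b in range(V):
            ub[self.iC(self.root, b)] = 0
            ub[self.iCbar(self.root, b)] = 0
        for s in range(2 * r):
            lb[self.iC(self.root, V + s)] = 1
            ub[self.iC(self.root, V + s)] = 1
        return Bounds(lb, ub)

    def integrality(self) -> np.ndarray:
        out = np.zeros(self.nvar)
        out[self.oC : self.oC + self.N * self.nc] = 1
        out[self.oCbar : self.oCbar + self.N * self.V] = 1
        out[self.oE : self.oE + self.N * self.N] = 1
        out[self.oA : self.oA + self.N * self.N] = 1
        out[self.oW : self.oW + self.N * self.N * self.V] = 1
        out[self.oD : self.oD + self.V] = 1
        return out

    # --- objective -------------------------------------------------------
    def objective(self, lam1: float, lam2: float) -> np.ndarray:
        c = np.zeros(self.nvar)
        c[self.oT : self.oT + self.m * self.nc] = 1.0
        c[self.oX : self.oX + 2 * self.N * self.N * self.r] = lam1
        c[self.oZ : self.oZ + self.m * self.V] = lam2
        return c

    # --- constraints -----------------------------------------------------
    def constraints(self) -> LinearConstraint:
        R = _Rows()
        N, V, r, m, nc = self.N, self.V, self.r, self.m, self.nc
        n, root, cmax = self.n, self.root, self.cmax
        seg_of = self.panel.segment_of
        M1 = 2 * cmax + 1
        M2 = 2 * cmax + 2
        pairs = list(self.edge_pairs())

        # tree: in-degree 1 (non-root), out-degree 2 (internal)
        for j in range(N - 1):
            cols = [self.iE(i, j) for i in range(n, N) if i != j]
            R.add(cols, [1.0] * len(cols), 1.0, 1.0)
        for i in range(n, N):
            cols = [self.iE(i, j) for j in range(N - 1) if j != i]
            R.add(cols, [1.0] * len(cols), 2.0, 2.0)
        # ancestry: A >= E, transitivity, antisymmetry, root ancestral to all
        for i, j in pairs:
            R.add([self.iA(i, j), self.iE(i, j)], [1.0, -1.0], 0.0, np.inf)
        for i in range(N):
            for j in range(N):
                if i < j:
                    R.add([self.iA(i, j), self.iA(j, i)], [1.0, 1.0], -np.inf, 1.0)
                for k in range(N):
                    if len({i, j, k}) == 3:
                        R.add(
                            [self.iA(i, k), self.iA(i, j), self.iA(j, k)],
                            [1.0, -1.0, -1.0], -1.0, np.inf,
                        )
        R.add([self.iA(root, j) for j in range(N - 1)], [1.0] * (N - 1), N - 1, N - 1)

        # data term: T[p,v] >= +-(F[p,v] - (UC)[p,v])
        for p in range(m):
            for v in range(nc):
                cols = [self.iC(k, v) for k in range(N)] + [self.iT(p, v)]
                R.add(cols, list(self.U[p]) + [1.0], self.F[p, v], np.inf)
                R.add(cols, list(-self.U[p]) + [1.0], -self.F[p, v], np.inf)

        # binarization of variant columns
        for k in range(N):
            for b in range(V):
                R.add([self.iC(k, b), self.iCbar(k, b)], [1.0, -1.0], 0.0, np.inf)
                R.add([self.iC(k, b), self.iCbar(k, b)], [1.0, -float(cmax)], -np.inf, 0.0)

        # Dollo: single gain; W tied to E and to the gain pattern; persistence
        for b in range(V):
            R.add([self.iW(i, j, b) for i, j in pairs], [1.0] * len(pairs), -np.inf, 1.0)
        for i, j in pairs:
            for b in range(V):
                R.add([self.iW(i, j, b), self.iE(i, j)], [1.0, -1.0], -np.inf, 0.0)
                R.add([self.iW(i, j, b), self.iCbar(i, b)], [1.0, 1.0], -np.inf, 1.0)
                R.add([self.iW(i, j, b), self.iCbar(j, b)], [1.0, -1.0], -np.inf, 0.0)
                # Cbar[j] <= Cbar[i] + W + (1 - E)
                R.add(
                    [self.iCbar(j, b), self.iCbar(i, b), self.iW(i, j, b), self.iE(i, j)],
                    [1.0, -1.0, -1.0, 1.0], -np.inf, 1.0,
                )

        # mate pairs share introduction edge and allele
        mate = self.panel.mate_of
        for b1 in range(self.panel.l):
            b2 = int(mate[b1])
            if b1 < b2:
                R.add([self.iD(b1), self.iD(b2)], [1.0, -1.0], 0.0, 0.0)
                for i, j in pairs:
                    R.add([self.iW(i, j, b1), self.iW(i, j, b2)], [1.0, -1.0], 0.0, 0.0)

        # per-edge absolute allele segment changes x (drive R)
        for i, j in pairs:
            for s in range(r):
                for a, off in ((0, V + s), (1, V + r + s)):
                    x = self.iX(a, i, j, s)
                    ci, cj = self.iC(i, off), self.iC(j, off)
                    R.add([x, self.iE(i, j)], [1.0, -float(cmax)], -np.inf, 0.0)
                    R.add([x, ci, cj, self.iE(i, j)], [1.0, -1.0, 1.0, -float(cmax)], -cmax, np.inf)
                    R.add([x, ci, cj, self.iE(i, j)], [1.0, 1.0, -1.0, -float(cmax)], -cmax, np.inf)

        # allele-phased coupling of variant copy change to segment change
        for i, j in pairs:
            for b in range(V):
                s = int(seg_of[b])
                g0i, g0j = self.iC(i, V + s), self.iC(j, V + s)
                g1i, g1j = self.iC(i, V + r + s), self.iC(j, V + r + s)
                cbi, cbj = self.iC(i, b), self.iC(j, b)
                e, w, d, cb = self.iE(i, j), self.iW(i, j, b), self.iD(b), self.iCbar(i, b)
                if self.cfg.phasing == "strict":
                    # gamma_j - gamma_i vs c_j - c_i, active iff e=1, w=0,
                    # the variant's allele matches, and it exists in parent i
                    R.add([g0j, g0i, cbj, cbi, e, d, w, cb],
                          [1, -1, -1, 1, -M1, -M1, M1, -M1], -3 * M1, np.inf)
                    R.add([g0j, g0i, cbj, cbi, e, d, w, cb],
                          [1, -1, -1, 1, M2, M2, -M2, M2], -np.inf, 3 * M2)
                    R.add([g1j, g1i, cbj, cbi, e, d, w, cb],
                          [1, -1, -1, 1, -M1, M1, M1, -M1], -2 * M1, np.inf)
                    R.add([g1j, g1i, cbj, cbi, e, d, w, cb],
                          [1, -1, -1, 1, M2, -M2, -M2, M2], -np.inf, 2 * M2)
                else:
                    # |c_j - c_i| <= x_allele when active
                    x0 = self.iX(0, i, j, s)
                    x1 = self.iX(1, i, j, s)
                    for sign in (1.0, -1.0):
                        R.add([cbj, cbi, x0, e, d, w, cb],
                              [sign, -sign, -1.0, M2, M2, -M2, M2], -np.inf, 3 * M2)
                        R.add([cbj, cbi, x1, e, d, w, cb],
                              [sign, -sign, -1.0, M2, -M2, -M2, M2], -np.inf, 2 * M2)

        # variant copy bounded by its allele's segment copy
        for k in range(N):
            for b in range(V):
                s = int(seg_of[b])
                R.add([self.iC(k, b), self.iC(k, V + s), self.iD(b)],
                      [1.0, -1.0, float(cmax)], -np.inf, cmax)
                R.add([self.iC(k, b), self.iC(k, V + r + s), self.iD(b)],
                      [1.0, -1.0, -float(cmax)], -np.inf, 0.0)

        # VAF-consistency slack z
        v = V
        seg_tot = self.F[:, v : v + r] + self.F[:, v + r :]
        psi = seg_tot[:, seg_of] if v else np.zeros((m, 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = np.where(psi > 0, self.F[:, :v] / np.where(psi > 0, psi, 1.0), 0.0)
        pi = np.clip(pi, 0.0, 1.0)
        for p in range(m):
            for b in range(V):
                if psi[p, b] <= 0:
                    continue  # no VAF information for this entry
                s = int(seg_of[b])
                cols = [self.iZ(p, b)]
                coefs = [1.0]
                for k in range(N):
                    u = self.U[p, k]
                    if u == 0.0:
                        continue
                    cols += [self.iC(k, V + s), self.iC(k, V + r + s), self.iC(k, b)]
                    coefs += [-pi[p, b] * u, -pi[p, b] * u, u]
                R.add(cols, coefs, 0.0, np.inf)
                coefs2 = [1.0] + [-x for x in coefs[1:]]
                R.add(cols, coefs2, 0.0, np.inf)

        self._pi = pi
        self._psi = psi
        A = R.matrix(self.nvar)
        return LinearConstraint(A, np.array(R.lb), np.array(R.ub))


def _normal_solution_vector(model: _CStepModel) -> np.ndarray:
    """The all-normal (diploid, variant-free) solution on a caterpillar tree."""
    x = np.zeros(model.nvar)
    N, n, V, r, nc = model.N, model.n, model.V, model.r, model.nc
    for k in range(N):
        for s in range(2 * r):
            x[model.iC(k, V + s)] = 1.0
    # caterpillar: internal i has children (leaf, next internal); deepest
    # internal has two leaves
    parents = np.full(N, -1)
    internals = list(range(N - 1, n - 1, -1))  # root first
    leaves = list(range(n))
    for idx, i in enumerate(internals):
        if idx + 1 < len(internals):
            parents[internals[idx + 1]] = i
            parents[leaves[idx]] = i
        else:
            parents[leaves[idx]] = i
            parents[leaves[idx + 1]] = i
    for j, i in enumerate(parents):
        if i >= 0:
            x[model.iE(i, j)] = 1.0
    # ancestry closure
    for j in range(N):
        i = parents[j]
        while i >= 0:
            x[model.iA(i, j)] = 1.0
            i = parents[i]
    # residual slack T at the observed F
    for p in range(model.m):
        for v in range(nc):
            pred = 1.0 if v >= V else 0.0
            x[model.iT(p, v)] = abs(model.F[p, v] - pred)
    # z slack at the normal profile: prediction of the constrained quantity
    pi, psi = model._pi, model._psi
    seg_of = model.panel.segment_of
    for p in range(model.m):
        for b in range(V):
            if psi[p, b] <= 0:
                continue
            x[model.iZ(p, b)] = abs(pi[p, b] * 2.0)  # gamma0+gamma1 = 2, c_b = 0
    return x


def solve_C_step(
    F: np.ndarray,
    U: np.ndarray,
    panel: VariantPanel,
    config: SolverConfig,
    lambdas: tuple[float, float] | None = None,
) -> tuple[CloneProfiles, CloneTree, float, float, bool]:
    """Solve the phylogeny-constrained integer program for C with U fixed.

    Returns (profiles, tree, R, S, proven_optimal). Raises
    :class:`SolverError` on proven infeasibility (a modeling bug: the
    all-normal solution is always feasible and is asserted first) or when no
    incumbent exists at the time limit.
    """
    model = _CStepModel(F, U, panel, config)
    if lambdas is None:
        lam1, lam2 = default_lambdas(panel.l, panel.g, panel.r, model.m, model.N)
    else:
        lam1, lam2 = lambdas
    if config.lambda1 is not None:
        lam1 = config.lambda1
    if config.lambda2 is not None:
        lam2 = config.lambda2
    cons = model.constraints()
    bounds = model.bounds()

    x0 = _normal_solution_vector(model)
    Ax = cons.A @ x0
    tol = 1e-7
    if (np.any(Ax < cons.lb - tol) or np.any(Ax > cons.ub + tol)
            or np.any(x0 < bounds.lb - tol) or np.any(x0 > bounds.ub + tol)):
        raise SolverError("internal modeling bug: the all-normal solution is infeasible")

    res = milp(
        c=model.objective(lam1, lam2),
        constraints=cons,
        integrality=model.integrality(),
        bounds=bounds,
        options={"time_limit": config.time_limit_per_iter,
                 "mip_rel_gap": config.mip_gap,
                 "disp": False},
    )
    if res.status == 2:
        raise SolverError("C-step proven infeasible: modeling bug")
    if res.x is None:
        raise SolverError(f"C-step returned no incumbent: {res.message}")
    x = res.x
    optimal = res.status == 0

    N, V, r, nc = model.N, model.V, model.r, model.nc
    C = np.rint([[x[model.iC(k, v)] for v in range(nc)] for k in range(N)]).astype(int)
    D = np.rint([x[model.iD(b)] for b in range(V)]).astype(np.int8)
    E = np.zeros((N, N), dtype=np.int8)
    W = np.zeros((N, N, V), dtype=np.int8)
    for i, j in model.edge_pairs():
        E[i, j] = int(round(x[model.iE(i, j)]))
        for b in range(V):
            W[i, j, b] = int(round(x[model.iW(i, j, b)]))
    tree = CloneTree(n=model.n, E=E, W=W)
    rho = np.zeros((N, N))
    for i, j in zip(*np.nonzero(E)):
        rho[i, j] = np.abs(C[j, V:] - C[i, V:]).sum()
    tree.rho = rho
    profiles = CloneProfiles(C=C, D=D, c_max=config.c_max)
    R_val = float(rho.sum())
    S_val = _S_term(model._pi, model._psi, model.U, C, panel)
    return profiles, tree, R_val, S_val, optimal


def _S_term(pi, psi, U, C, panel: VariantPanel) -> float:
    V, r = panel.n_variants, panel.r
    if V == 0:
        return 0.0
    seg = panel.segment_of
    gam_tot = C[:, V + seg] + C[:, V + r + seg]  # (N, V)
    pred_seg = U @ gam_tot
    pred_var = U @ C[:, :V]
    s = np.abs(pi * pred_seg - pred_var)
    return float(s[psi > 0].sum())


def compute_objective(
    F: np.ndarray,
    U: np.ndarray,
    profiles: CloneProfiles,
    tree: CloneTree,
    panel: VariantPanel,
    lam1: float,
    lam2: float,
) -> dict:
    """Recompute all objective components outside any solver."""
    F = np.asarray(F, dtype=float)
    C = profiles.C
    data = float(np.abs(F - U @ C).sum())
    V, r = panel.n_variants, panel.r
    Rv = 0.0
    for i, j in zip(*np.nonzero(tree.E)):
        Rv += float(np.abs(C[j, V:] - C[i, V:]).sum())
    seg_tot = F[:, V : V + r] + F[:, V + r :]
    psi = seg_tot[:, panel.segment_of] if V else np.zeros((F.shape[0], 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(psi > 0, F[:, :V] / np.where(psi > 0, psi, 1.0), 0.0)
    pi = np.clip(pi, 0.0, 1.0)
    Sv = _S_term(pi, psi, U, C, panel)
    return {
        "objective": data + lam1 * Rv + lam2 * Sv,
        "data": data,
        "R": Rv,
        "S": Sv,
        "lambda1": lam1,
        "lambda2": lam2,
    }


# ---------------------------------------------------------------------------
# Coordinate descent
# ---------------------------------------------------------------------------

def coordinate_descent(
    F: np.ndarray | BulkObservation,
    panel: VariantPanel,
    config: SolverConfig,
) -> SolveResult:
    """Alternate C-step and U-step from random simplex initializations.

    Runs ``config.n_restarts`` restarts (each with its own spawned seed),
    alternating the MILP C-step and LP U-step until the relative objective
    improvement drops below ``convergence_tol`` or ``max_iters`` is reached;
    returns the restart with the best final objective, with the full
    per-iteration trace. A failed restart is logged and skipped; only if all
    restarts fail is an error raised.
    """
    if isinstance(F, BulkObservation):
        F = F.F
    F = np.asarray(F, dtype=float)
    m = F.shape[0]
    N = 2 * config.n_leaves - 1
    lam1, lam2 = default_lambdas(panel.l, panel.g, panel.r, m, N)
    if config.lambda1 is not None:
        lam1 = config.lambda1
    if config.lambda2 is not None:
        lam2 = config.lambda2

    master = np.random.default_rng(config.seed)
    restart_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=config.n_restarts)]
    best: SolveResult | None = None
    errors: list[str] = []
    for rs in restart_seeds:
        rng = np.random.default_rng(rs)
        U = rng.dirichlet(np.ones(N), size=m)
        if config.leaf_only:
            keep = list(range(config.n_leaves)) + [N - 1]
            U2 = np.zeros_like(U)
            U2[:, keep] = rng.dirichlet(np.ones(len(keep)), size=m)
            U = U2
        trace: list[dict] = []
        prev_obj = np.inf
        sol = None
        try:
            for it in range(config.max_iters):
                profiles, tree, Rv, Sv, optimal = solve_C_step(
                    F, U, panel, config, lambdas=(lam1, lam2)
                )
                freqs = solve_U_step(F, profiles.C, config.n_leaves, config.leaf_only)
                U = freqs.U
                comp = compute_objective(F, U, profiles, tree, panel, lam1, lam2)
                comp["iteration"] = it
                comp["c_step_optimal"] = optimal
                comp["restart_seed"] = rs
                trace.append(comp)
                obj = comp["objective"]
                sol = (tree, profiles, freqs, comp, optimal)
                if prev_obj < np.inf and (
                    prev_obj - obj <= config.convergence_tol * max(1.0, abs(prev_obj))
                ):
                    break
                prev_obj = obj
        except SolverError as exc:
            errors.append(str(exc))
            continue
        if sol is None:
            continue
        tree, profiles, freqs, comp, optimal = sol
        result = SolveResult(
            tree=tree, profiles=profiles, freqs=freqs,
            objective=comp["objective"], data_term=comp["data"],
            R=comp["R"], S=comp["S"], trace=trace, optimal=optimal,
            restart_seeds=restart_seeds,
        )
        if best is None or result.objective < best.objective - 1e-12:
            best = result
    if best is None:
        raise SolverError("all restarts failed: " + "; ".join(errors))
    return best


# ---------------------------------------------------------------------------
# Clone-number heuristic
# ---------------------------------------------------------------------------

@dataclass
class CollapsedTree:
    """Collapsed clone tree: parents map over surviving node ids, merged U."""

    parents: dict[int, int]
    U: np.ndarray  # (m, N) with mass only on surviving nodes
    n_clones: int
    merged_into: dict[int, int] = field(default_factory=dict)


def collapse_tree(result: SolveResult, freq_tol: float = 1e-6) -> tuple[CollapsedTree, int]:
    """Estimate the clone number by collapsing redundant nodes.

    Iteratively (i) removes zero-total-frequency nodes that have exactly one
    child, reattaching the child to the grandparent, and (ii) merges children
    whose incoming branch has zero copy-number length and introduces no
    variant into their parent (frequencies summed). Idempotent.
    """
    tree, U = result.tree, result.freqs.U.copy()
    N = tree.N
    parents = {int(j): int(i) for i, j in zip(*np.nonzero(tree.E))}
    alive = set(range(N))
    rho_m = tree.rho if tree.rho is not None else np.zeros((N, N))
    wsum_m = tree.W.sum(axis=2) if tree.W is not None else np.zeros((N, N))
    # per-node incoming-branch stats; reattachments accumulate them so a
    # spliced-out node's branch length is not lost
    blen = {j: float(rho_m[parents[j], j]) for j in parents}
    bvar = {j: float(wsum_m[parents[j], j]) for j in parents}
    merged: dict[int, int] = {}

    def children_of(i):
        return [j for j, p in parents.items() if p == i and j in alive]

    changed = True
    while changed:
        changed = False
        for j in sorted(alive):
            if j == tree.root or j not in alive:
                continue
            p = parents[j]
            ch = children_of(j)
            tot = float(U[:, j].sum())
            if tot <= freq_tol and len(ch) == 1:
                c = ch[0]
                parents[c] = p
                blen[c] += blen[j]
                bvar[c] += bvar[j]
                alive.discard(j)
                merged[j] = p
                changed = True
            elif blen[j] == 0 and bvar[j] == 0:
                # zero-length branch: child is the same clone as its parent
                U[:, p] += U[:, j]
                U[:, j] = 0.0
                for c in ch:
                    parents[c] = p
                alive.discard(j)
                merged[j] = p
                changed = True
    out_parents = {j: parents[j] for j in alive if j != tree.root}
    collapsed = CollapsedTree(
        parents=out_parents, U=U, n_clones=len(alive), merged_into=merged
    )
    return collapsed, len(alive)
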