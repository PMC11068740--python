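"""Thin LP/MILP layer over scipy's HiGHS interface (and optlang-GLPK).

The rest of the package expresses every optimisation as a
:class:`LinearProblem` — variables with bounds, equality/inequality rows,
a linear objective, optionally a set of binary variables — and hands it to
:func:`solve_lp` / :func:`solve_milp`. Two backends are supported:

* ``highs`` (default): ``scipy.optimize.linprog`` / ``scipy.optimize.milp``;
* ``glpk``: optlang's GLPK interface, used as an independent cross-check.

Feasibility and integrality tolerance is 1e-6 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, linprog, milp

FEASIBILITY_TOL = 1e-6
DEFAULT_BACKEND = "highs"

_LINPROG_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}
_MILP_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


@dataclass
class SolveResult:
    status: str  # optimal | infeasible | unbounded | error
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    membership: dict[str, int] | None = None
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class LinearProblem:
    """A linear (or mixed-integer) program under construction.

    Variables are named; rows are sparse coefficient dicts. A sparse base
    equality block (typically the stoichiometric matrix, rhs 0) can be
    attached wholesale for efficiency.
    """

    def __init__(self, names: list[str], lb: np.ndarray, ub: np.ndarray):
        self.names = list(names)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.lb = np.asarray(lb, dtype=float).copy()
        self.ub = np.asarray(ub, dtype=float).copy()
        if len(self.lb) != len(self.names) or len(self.ub) != len(self.names):
            raise ValueError("bounds do not match variable count")
        self.obj: dict[str, float] = {}
        self.sense = "max"
        self.base_eq: sparse.spmatrix | None = None  # rows with rhs 0
        self.eq_rows: list[tuple[dict[str, float], float]] = []
        self.ub_rows: list[tuple[dict[str, float], float]] = []
        self.integers: set[str] = set()

    # -- construction ----------------------------------------------------
    def add_variable(self, name: str, lb: float, ub: float, binary: bool = False) -> None:
        if name in self.index:
            raise ValueError(f"duplicate variable {name!r}")
        self.index[name] = len(self.names)
        self.names.append(name)
        self.lb = np.append(self.lb, lb)
        self.ub = np.append(self.ub, ub)
        if binary:
            if not (0 <= lb and ub <= 1):
                raise ValueError(f"binary variable {name!r} needs bounds within [0, 1]")
            self.integers.add(name)

    def set_objective(self, coeffs: dict[str, float], sense: str = "max") -> None:
        if sense not in {"max", "min"}:
            raise ValueError(f"sense must be max or min, got {sense!r}")
        self._check_vars(coeffs)
        self.obj = dict(coeffs)
        self.sense = sense

    def add_eq(self, coeffs: dict[str, float], rhs: float) -> None:
        self._check_vars(coeffs)
        self.eq_rows.append((dict(coeffs), float(rhs)))

    def add_le(self, coeffs: dict[str, float], rhs: float) -> None:
        """Add a row  Σ c_i x_i ≤ rhs."""
        self._check_vars(coeffs)
        self.ub_rows.append((dict(coeffs), float(rhs)))

    def add_ge(self, coeffs: dict[str, float], rhs: float) -> None:
        """Add a row  Σ c_i x_i ≥ rhs (stored as its ≤ negation)."""
        self.add_le({k: -v for k, v in coeffs.items()}, -rhs)

    def _check_vars(self, coeffs: dict[str, float]) -> None:
        missing = [k for k in coeffs if k not in self.index]
        if missing:
            raise KeyError(f"unknown variables {missing}")

    # -- assembly --------------------------------------------------------
    def _rows_to_matrix(self, rows: list[tuple[dict[str, float], float]]):
        n = len(self.names)
        if not rows:
            return sparse.csr_matrix((0, n)), np.zeros(0)
        ri, ci, vv, rhs = [], [], [], []
        for r, (coeffs, b) in enumerate(rows):
            rhs.append(b)
            for name, v in coeffs.items():
                ri.append(r)
                ci.append(self.index[name])
                vv.append(v)
        A = sparse.csr_matrix((vv, (ri, ci)), shape=(len(rows), n))
        return A, np.array(rhs)

    def assemble(self):
        """Return (c, A_eq, b_eq, A_ub, b_ub, lb, ub, integrality) for a minimiser."""
        n = len(self.names)
        c = np.zeros(n)
        for name, v in self.obj.items():
            c[self.index[name]] = v
        if self.sense == "max":
            c = -c
        A_extra, b_extra = self._rows_to_matrix(self.eq_rows)
        if self.base_eq is not None:
            base = sparse.csr_matrix(self.base_eq)
            if base.shape[1] < n:  # variables appended after the base block
                pad = sparse.csr_matrix((base.shape[0], n - base.shape[1]))
                base = sparse.hstack([base, pad], format="csr")
            A_eq = sparse.vstack([base, A_extra], format="csr")
            b_eq = np.concatenate([np.zeros(base.shape[0]), b_extra])
        else:
            A_eq, b_eq = A_extra, b_extra
        A_ub, b_ub = self._rows_to_matrix(self.ub_rows)
        integrality = np.zeros(n)
        for name in self.integers:
            integrality[self.index[name]] = 1
        return c, A_eq, b_eq, A_ub, b_ub, self.lb.copy(), self.ub.copy(), integrality


def _result_from_x(p: LinearProblem, x: np.ndarray) -> SolveResult:
    fluxes = {name: float(x[i]) for i, name in enumerate(p.names)}
    obj = sum(p.obj.get(name, 0.0) * fluxes[name] for name in p.obj)
    membership = None
    if p.integers:
        membership = {}
        for name in sorted(p.integers):
            v = fluxes[name]
            membership[name] = int(round(v))
            fluxes[name] = float(round(v))
    return SolveResult(status="optimal", objective_value=float(obj), fluxes=fluxes, membership=membership)


def solve_lp(p: LinearProblem, backend: str = DEFAULT_BACKEND) -> SolveResult:
    """Solve a pure LP. Deterministic for a fixed problem and backend."""
    if p.integers:
        raise ValueError("problem has integer variables; use solve_milp")
    if backend == "glpk":
        return _solve_optlang(p)
    c, A_eq, b_eq, A_ub, b_ub, lb, ub, _ = p.assemble()
    res = linprog(
        c,
        A_ub=A_ub if A_ub.shape[0] else None,
        b_ub=b_ub if A_ub.shape[0] else None,
        A_eq=A_eq if A_eq.shape[0] else None,
        b_eq=b_eq if A_eq.shape[0] else None,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _LINPROG_STATUS.get(res.status, "error")
    if status != "optimal":
        return SolveResult(status=status, objective_value=np.nan, message=res.message)
    return _result_from_x(p, res.x)


def solve_milp(p: LinearProblem, backend: str = DEFAULT_BACKEND) -> SolveResult:
    """Solve a MILP to global optimality (gap tolerance 1e-6 absolute)."""
    if not p.integers:
        raise ValueError("problem has no integer variables; use solve_lp")
    if backend == "glpk":
        return _solve_optlang(p)
    c, A_eq, b_eq, A_ub, b_ub, lb, ub, integrality = p.assemble()
    constraints = []
    if A_eq.shape[0]:
        constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
    if A_ub.shape[0]:
        constraints.append(LinearConstraint(A_ub, -np.inf, b_ub))
    from scipy.optimize import Bounds

    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"mip_rel_gap": 0.0},
    )
    status = _MILP_STATUS.get(res.status, "error")
    if status != "optimal" or res.x is None:
        return SolveResult(status=status, objective_value=np.nan, message=res.message)
    return _result_from_x(p, res.x)


def _solve_optlang(p: LinearProblem) -> SolveResult:
    """GLPK backend (via optlang); handles both LP and MILP."""
    from optlang import glpk_interface as glpk

    model = glpk.Model()
    variables = {}
    for i, name in enumerate(p.names):
        vtype = "binary" if name in p.integers else "continuous"
        lb = None if np.isneginf(p.lb[i]) else float(p.lb[i])
        ub = None if np.isposinf(p.ub[i]) else float(p.ub[i])
        variables[name] = glpk.Variable(name, lb=lb, ub=ub, type=vtype)
    model.add(list(variables.values()))
    model.update()

    constraints = []
    if p.base_eq is not None:
        base = sparse.csr_matrix(p.base_eq)
        for r in range(base.shape[0]):
            row = base.getrow(r)
            expr = sum(float(v) * variables[p.names[j]] for j, v in zip(row.indices, row.data))
            constraints.append(glpk.Constraint(expr, lb=0, ub=0))
    for coeffs, rhs in p.eq_rows:
        expr = sum(v * variables[k] for k, v in coeffs.items())
        constraints.append(glpk.Constraint(expr, lb=rhs, ub=rhs))
    for coeffs, rhs in p.ub_rows:
        expr = sum(v * variables[k] for k, v in coeffs.items())
        constraints.append(glpk.Constraint(expr, ub=rhs))
    model.add(constraints)
    objective = sum(v * variables[k] for k, v in p.obj.items())
    model.objective = glpk.Objective(objective, direction=p.sense)
    status = model.optimize()
    if status != "optimal":
        mapped = status if status in {"infeasible", "unbounded"} else "error"
        return SolveResult(status=mapped, objective_value=np.nan, message=str(status))
    x = np.array([variables[name].primal for name in p.names])
    return _result_from_x(p, x)


def community_lp(comm, objective: dict[str, float], sense: str = "max") -> LinearProblem:
    """Assemble the LP skeleton of a community model.

    Mass balance (``S v = 0``, including the pool rows that sum member
    exchanges into the community exchange), current bounds (deleted members
    already have 0/0), and any coupling rows attached to the community.
    """
    p = LinearProblem(comm.reactions, comm.lb, comm.ub)
    p.base_eq = comm.S
    for row in comm.couplings:
        p.add_le({row.rxn: row.sign, comm.biomass[row.species]: -row.c}, row.u)
    p.set_objective(objective, sense)
    return p
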