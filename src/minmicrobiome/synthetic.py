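"""Synthetic cross-feeding communities with analytically known structure.

The toys emulate the trophic chain of a fibre-fermenting gut community:

* a **degrader** imports dietary fibre and breaks it into a monomer
  (growing on the side) — nothing else can touch fibre;
* **SCFA producers** import the monomer and split it between a pure growth
  reaction and a fermentation reaction that yields one SCFA (acetate,
  butyrate or propionate) plus less biomass, so growth and SCFA production
  compete for substrate;
* **cross-feeders** convert monomer to lactate plus biomass;
* **freeloaders** grow on the monomer without producing anything.

All yields are small halves/integers, so LP optima are exact rationals.

The module also carries the **brute-force oracle**: an exhaustive
minimal-subset search whose constraint matrices are assembled here, densely
and independently of the community/solve/workflow code paths, so agreement
with the MILP is evidence rather than tautology.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from minmicrobiome.community import CommunityModel, DEFAULT_COUPLING_C, DEFAULT_COUPLING_U
from minmicrobiome.model_io import Diet, MicrobeModel
from minmicrobiome.workflow import (
    FunctionalitySpec,
    MinimalMicrobiome,
    Targets,
    THRESHOLD_SLACK,
    prepare_community,
)
from scipy import sparse

ORACLE_GUARD = 12

SCFA_MET = {"acetate": "ac(e)", "butyrate": "but(e)", "propionate": "ppa(e)"}
SCFA_EXCHANGE = {name: f"EX_{met}" for name, met in SCFA_MET.items()}

ROLES = ("degrader", "acetate_producer", "butyrate_producer", "propionate_producer",
         "cross_feeder", "freeloader")


@dataclass(frozen=True)
class MemberSpec:
    role: str
    uptake: float = 4.0       # substrate uptake bound, mmol/gDW-h
    product_yield: float = 1.0  # product per substrate (monomer, SCFA or lactate)
    growth_yield: float = 1.0   # biomass per substrate via the growth route
    ferment_growth_yield: float | None = None  # biomass per substrate while fermenting


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a toy community."""

    members: tuple[MemberSpec, ...]
    fibre_supply: float = 10.0
    seed: int = 0

    @property
    def n(self) -> int:
        return len(self.members)

    def __post_init__(self) -> None:
        roles = [m.role for m in self.members]
        bad = [r for r in roles if r not in ROLES]
        if bad:
            raise ValueError(f"unknown roles {bad}")
        for m in self.members:
            if m.product_yield <= 0 or m.growth_yield <= 0:
                raise ValueError("yields must be positive")


@dataclass
class OracleReport:
    """Exhaustive subset search results."""

    feasible_subsets: list[tuple[frozenset, float, float]]  # (subset, max growth, max SCFA)
    minimal_supports: list[frozenset]
    min_cardinality: int
    subsets_tested: int = 0


# ---------------------------------------------------------------------------
# toy construction
# ---------------------------------------------------------------------------

def make_toy_member(spec: MemberSpec, member_id: str) -> MicrobeModel:
    """Build one 3-6 reaction member model for the given role."""
    role = spec.role
    yf = spec.ferment_growth_yield
    if yf is None:
        yf = spec.growth_yield / 2.0
    if role == "degrader":
        mets = ["fibre(e)", "monomer(e)", "bio(c)"]
        rxns = {
            "EX_fibre(e)": ({"fibre(e)": -1.0}, (-spec.uptake, 1000.0)),
            "DEGRADE": (
                {"fibre(e)": -1.0, "monomer(e)": spec.product_yield, "bio(c)": spec.growth_yield},
                (0.0, 1000.0),
            ),
            f"biomass_{member_id}": ({"bio(c)": -1.0}, (0.0, 1000.0)),
            "EX_monomer(e)": ({"monomer(e)": -1.0}, (-1000.0, 1000.0)),
        }
        exchanges = [("EX_fibre(e)", "fibre(e)"), ("EX_monomer(e)", "monomer(e)")]
    elif role.endswith("_producer"):
        scfa = role.removesuffix("_producer")
        pmet = SCFA_MET[scfa]
        mets = ["monomer(e)", pmet, "bio(c)"]
        rxns = {
            "EX_monomer(e)": ({"monomer(e)": -1.0}, (-spec.uptake, 1000.0)),
            "GROW": ({"monomer(e)": -1.0, "bio(c)": spec.growth_yield}, (0.0, 1000.0)),
            "FERMENT": (
                {"monomer(e)": -1.0, pmet: spec.product_yield, "bio(c)": yf},
                (0.0, 1000.0),
            ),
            f"biomass_{member_id}": ({"bio(c)": -1.0}, (0.0, 1000.0)),
            SCFA_EXCHANGE[scfa]: ({pmet: -1.0}, (-1000.0, 1000.0)),
        }
        exchanges = [("EX_monomer(e)", "monomer(e)"), (SCFA_EXCHANGE[scfa], pmet)]
    elif role == "cross_feeder":
        mets = ["monomer(e)", "lac(e)", "bio(c)"]
        rxns = {
            "EX_monomer(e)": ({"monomer(e)": -1.0}, (-spec.uptake, 1000.0)),
            "CONVERT": (
                {"monomer(e)": -1.0, "lac(e)": spec.product_yield, "bio(c)": spec.growth_yield},
                (0.0, 1000.0),
            ),
            f"biomass_{member_id}": ({"bio(c)": -1.0}, (0.0, 1000.0)),
            "EX_lac(e)": ({"lac(e)": -1.0}, (-1000.0, 1000.0)),
        }
        exchanges = [("EX_monomer(e)", "monomer(e)"), ("EX_lac(e)", "lac(e)")]
    elif role == "freeloader":
        mets = ["monomer(e)", "bio(c)"]
        rxns = {
            "EX_monomer(e)": ({"monomer(e)": -1.0}, (-spec.uptake, 1000.0)),
            "GROW": ({"monomer(e)": -1.0, "bio(c)": spec.growth_yield}, (0.0, 1000.0)),
            f"biomass_{member_id}": ({"bio(c)": -1.0}, (0.0, 1000.0)),
        }
        exchanges = [("EX_monomer(e)", "monomer(e)")]
    else:
        raise ValueError(f"unknown role {role!r}")

    rxn_ids = list(rxns)
    met_index = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        coeffs, (lo, hi) = rxns[rid]
        lb[j], ub[j] = lo, hi
        for m, v in coeffs.items():
            S[met_index[m], j] = v
    model = MicrobeModel(
        id=member_id,
        metabolites=mets,
        reactions=rxn_ids,
        S=sparse.csc_matrix(S),
        lb=lb,
        ub=ub,
        biomass_rxn=f"biomass_{member_id}",
        exchange_rxns=exchanges,
    )
    model.validate()
    return model


def toy_models(spec: ToySpec) -> list[MicrobeModel]:
    counts: dict[str, int] = {}
    models = []
    for m in spec.members:
        counts[m.role] = counts.get(m.role, 0) + 1
        short = {"degrader": "deg", "acetate_producer": "acp", "butyrate_producer": "butp",
                 "propionate_producer": "ppap", "cross_feeder": "xf", "freeloader": "free"}[m.role]
        models.append(make_toy_member(m, f"{short}{counts[m.role]}"))
    return models


def toy_diet(spec: ToySpec) -> Diet:
    return Diet(bounds={"EX_fibre(e)": (-spec.fibre_supply, 1000.0)}, name=f"fibre_{spec.fibre_supply:g}")


def make_toy_community(
    spec: ToySpec,
    coupling_c: float = DEFAULT_COUPLING_C,
    coupling_u: float = DEFAULT_COUPLING_U,
) -> tuple[CommunityModel, dict]:
    """Build the community (fibre-only diet, coupling on) plus ground truth.

    The annotations record which members degrade fibre and which can
    contribute to each SCFA.
    """
    models = toy_models(spec)
    comm = prepare_community(models, toy_diet(spec), coupling_c, coupling_u, "closed")
    annotations: dict = {"degraders": [], "producers": {s: [] for s in SCFA_MET}}
    for member, model in zip(spec.members, models):
        if member.role == "degrader":
            annotations["degraders"].append(model.id)
        elif member.role.endswith("_producer"):
            annotations["producers"][member.role.removesuffix("_producer")].append(model.id)
    return comm, annotations


# -- named fixtures ---------------------------------------------------------

def toy_3() -> tuple[CommunityModel, dict]:
    """Degrader → butyrate producer chain plus one freeloader.

    Unique minimal support at the default thresholds: {deg1, butp1}.
    """
    return make_toy_community(ToySpec(members=(
        MemberSpec("degrader", uptake=5.0, product_yield=2.0, growth_yield=0.5),
        MemberSpec("butyrate_producer", uptake=10.0, product_yield=1.0, growth_yield=1.0),
        MemberSpec("freeloader", uptake=10.0, growth_yield=0.5),
    ), fibre_supply=5.0, seed=3))


def toy_5_redundant() -> tuple[CommunityModel, dict]:
    """Two interchangeable butyrate producers: two minimal supports of size 2."""
    producer = MemberSpec("butyrate_producer", uptake=10.0, product_yield=1.0, growth_yield=1.0)
    return make_toy_community(ToySpec(members=(
        MemberSpec("degrader", uptake=5.0, product_yield=2.0, growth_yield=0.5),
        producer,
        producer,
        MemberSpec("freeloader", uptake=10.0, growth_yield=0.5),
        MemberSpec("freeloader", uptake=10.0, growth_yield=0.5),
    ), fibre_supply=5.0, seed=5))


def toy_9_demo() -> tuple[CommunityModel, dict]:
    """Nine members: four butyrate producers of unequal yield plus five others.

    Mirrors the demonstration design of a community with redundant butyrate
    producers; the highest-yield producer plus the degrader carry the
    butyrate functionality.
    """
    return make_toy_community(ToySpec(members=(
        MemberSpec("degrader", uptake=6.0, product_yield=2.0, growth_yield=0.5),
        MemberSpec("butyrate_producer", uptake=12.0, product_yield=2.0, growth_yield=1.0),
        MemberSpec("butyrate_producer", uptake=12.0, product_yield=1.0, growth_yield=1.0),
        MemberSpec("butyrate_producer", uptake=6.0, product_yield=0.5, growth_yield=1.0),
        MemberSpec("butyrate_producer", uptake=6.0, product_yield=0.5, growth_yield=0.5),
        MemberSpec("acetate_producer", uptake=12.0, product_yield=1.0, growth_yield=1.0),
        MemberSpec("cross_feeder", uptake=6.0, product_yield=1.0, growth_yield=0.5),
        MemberSpec("freeloader", uptake=12.0, growth_yield=0.5),
        MemberSpec("freeloader", uptake=12.0, growth_yield=0.5),
    ), fibre_supply=12.0, seed=9))


def random_toy(seed: int, n: int | None = None) -> tuple[CommunityModel, dict]:
    """A seeded random toy: one degrader, ≥1 producer, mixed other roles."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(3, 9))
    if n < 3:
        raise ValueError("need at least 3 members")
    halves = lambda lo, hi: float(rng.integers(int(lo * 2), int(hi * 2) + 1)) / 2.0
    producers = ["acetate_producer", "butyrate_producer", "propionate_producer"]
    roles = ["degrader", str(rng.choice(producers))]
    extra = ["freeloader", "cross_feeder"] + producers
    roles += [str(rng.choice(extra)) for _ in range(n - 2)]
    members = []
    for role in roles:
        members.append(MemberSpec(
            role=role,
            uptake=halves(2, 6),
            product_yield=halves(0.5, 2.5),
            growth_yield=halves(0.5, 2),
        ))
    spec = ToySpec(members=tuple(members), fibre_supply=halves(4, 12), seed=seed)
    return make_toy_community(spec)


# ---------------------------------------------------------------------------
# independent dense assembly (oracle side)
# ---------------------------------------------------------------------------

class _DenseSystem:
    """Dense LP data for a community, assembled with plain loops.

    Deliberately shares no code with community/solve: variables are ordered
    member-by-member then community exchanges, matrices are dense numpy
    arrays, coupling rows are built from scratch from (c, u).
    """

    def __init__(self, comm: CommunityModel):
        models = comm.source_models
        self.members = [m.id for m in models]
        names: list[str] = []
        met_names: list[str] = []
        self.var_species: list[int] = []
        self.biomass_col: dict[int, int] = {}
        pool_of_ex: dict[str, str] = {}
        entries: list[tuple[str, str, float]] = []  # (met, var, coeff)
        for k, model in enumerate(models, start=1):
            suffix = f"_org{k}"
            ex_met = dict(model.exchange_rxns)
            dense = model.S.toarray()
            for j, rid in enumerate(model.reactions):
                var = rid + suffix
                names.append(var)
                self.var_species.append(k)
                if rid == model.biomass_rxn:
                    self.biomass_col[k] = len(names) - 1
                for i, mid in enumerate(model.metabolites):
                    if dense[i, j] != 0.0:
                        entries.append((mid + suffix, var, float(dense[i, j])))
                if rid in ex_met:
                    pool = "pool:" + ex_met[rid]
                    entries.append((pool, var, 1.0))
                    pool_of_ex.setdefault(rid, pool)
        self.community_ex_col: dict[str, int] = {}
        for ex_id, pool in pool_of_ex.items():
            names.append(ex_id)
            self.var_species.append(0)
            self.community_ex_col[ex_id] = len(names) - 1
            entries.append((pool, ex_id, -1.0))
        self.names = names
        col = {v: i for i, v in enumerate(names)}
        for met, _, _ in entries:
            if met not in met_names:
                met_names.append(met)
        row = {m: i for i, m in enumerate(met_names)}
        self.A_eq = np.zeros((len(met_names), len(names)))
        for met, var, coeff in entries:
            self.A_eq[row[met], col[var]] += coeff

        # bounds: member bounds from the raw models, community exchanges from the diet
        lb = np.empty(len(names))
        ub = np.empty(len(names))
        i = 0
        for k, model in enumerate(models, start=1):
            for j in range(len(model.reactions)):
                lb[i], ub[i] = model.lb[j], model.ub[j]
                i += 1
        diet = comm.diet.bounds if comm.diet is not None else {}
        for ex_id, c in self.community_ex_col.items():
            if ex_id in diet:
                lb[c], ub[c] = diet[ex_id]
            else:
                lb[c] = 0.0 if comm.diet_policy == "closed" else -1000.0
                ub[c] = 1000.0
        self.lb, self.ub = lb, ub
        self.var_species = np.array(self.var_species)

        # coupling: ±v_j − c·v_bio ≤ u for every non-biomass member flux
        rows = []
        if comm.coupling_params is not None:
            c_val, u_val = comm.coupling_params
            for idx, var in enumerate(names):
                k = self.var_species[idx]
                if k == 0 or idx == self.biomass_col[k]:
                    continue
                for sign in (+1.0, -1.0):
                    r = np.zeros(len(names))
                    r[idx] = sign
                    r[self.biomass_col[k]] -= c_val
                    rows.append((r, u_val))
        self.A_ub = np.array([r for r, _ in rows]) if rows else np.zeros((0, len(names)))
        self.b_ub = np.array([b for _, b in rows])

    def bounds_for_subset(self, subset: frozenset) -> np.ndarray:
        """Per-variable (lb, ub) with non-members' fluxes pinned to 0."""
        lb, ub = self.lb.copy(), self.ub.copy()
        keep = np.array([k == 0 or self.members[k - 1] in subset for k in self.var_species])
        lb[~keep] = 0.0
        ub[~keep] = 0.0
        return np.column_stack([lb, ub])

    def maximize(self, obj: np.ndarray, bounds: np.ndarray, extra_ub=None):
        """max obj·v; returns optimum or None if infeasible."""
        A_ub, b_ub = self.A_ub, self.b_ub
        if extra_ub is not None:
            rows, rhs = extra_ub
            A_ub = np.vstack([A_ub, rows]) if A_ub.size else np.asarray(rows)
            b_ub = np.concatenate([b_ub, rhs])
        res = linprog(
            -obj,
            A_ub=A_ub if len(b_ub) else None,
            b_ub=b_ub if len(b_ub) else None,
            A_eq=self.A_eq,
            b_eq=np.zeros(self.A_eq.shape[0]),
            bounds=bounds,
            method="highs",
        )
        if res.status != 0:
            return None
        return -res.fun

    def biomass_objective(self, subset: frozenset) -> np.ndarray:
        obj = np.zeros(len(self.names))
        for k, colk in self.biomass_col.items():
            if self.members[k - 1] in subset:
                obj[colk] = 1.0
        return obj

    def scfa_objective(self, spec: FunctionalitySpec) -> np.ndarray:
        obj = np.zeros(len(self.names))
        for ex_id, w in zip(spec.scfa_exchange_ids, spec.effective_weights):
            if w != 0 and ex_id in self.community_ex_col:
                obj[self.community_ex_col[ex_id]] += w
        return obj


def _subset_metrics(
    system: _DenseSystem,
    subset: frozenset,
    spec: FunctionalitySpec,
    targets: Targets,
) -> tuple[bool, float, float | None]:
    """(feasible at the thresholds, max growth, max SCFA at growth floor)."""
    bounds = system.bounds_for_subset(subset)
    bio = system.biomass_objective(subset)
    growth = system.maximize(bio, bounds)
    if growth is None:
        return False, -np.inf, None
    if targets.growth_constraint_mode == "community":
        growth_rows = (np.array([-bio]), np.array([-targets.growth_threshold]))
        if growth < targets.growth_threshold - THRESHOLD_SLACK:
            return False, growth, None
    else:
        rows, rhs = [], []
        for k, colk in system.biomass_col.items():
            sp = system.members[k - 1]
            if sp in subset:
                r = np.zeros(len(system.names))
                r[colk] = -1.0
                rows.append(r)
                rhs.append(-targets.gr_frac * targets.theta_k.get(sp, 0.0))
        growth_rows = (np.array(rows), np.array(rhs)) if rows else None
        if growth_rows is not None:
            if system.maximize(bio, bounds, extra_ub=growth_rows) is None:
                return False, growth, None
    scfa_obj = system.scfa_objective(spec)
    scfa = system.maximize(scfa_obj, bounds, extra_ub=growth_rows)
    if scfa is None:
        return False, growth, None
    feasible = scfa >= targets.scfa_threshold - THRESHOLD_SLACK
    return feasible, growth, scfa


def brute_force_minimal(
    comm: CommunityModel,
    spec: FunctionalitySpec,
    targets: Targets,
    min_cardinality_only: bool = False,
) -> OracleReport:
    """Exhaustive minimal-subset search over the active members.

    Every nonempty subset of the active members is tested by direct dense
    LPs (growth, then SCFA at the growth floor). With
    ``min_cardinality_only`` the search walks cardinalities upward and stops
    once the smallest feasible level is fully enumerated. Degenerate zero
    thresholds give the empty support, matching the workflow convention.
    """
    active = [comm.members[k - 1] for k in comm.active_members()]
    if len(active) > ORACLE_GUARD:
        raise ValueError(f"oracle guard: {len(active)} active members > {ORACLE_GUARD}")
    if (targets.growth_threshold <= THRESHOLD_SLACK
            and targets.scfa_threshold <= THRESHOLD_SLACK):
        return OracleReport([(frozenset(), 0.0, 0.0)], [frozenset()], 0, 0)
    system = _DenseSystem(comm)
    feasible: list[tuple[frozenset, float, float]] = []
    minimal: list[frozenset] = []
    min_card = None
    tested = 0
    for size in range(1, len(active) + 1):
        if min_card is not None and min_cardinality_only:
            break
        for combo in itertools.combinations(active, size):
            subset = frozenset(combo)
            tested += 1
            ok, growth, scfa = _subset_metrics(system, subset, spec, targets)
            if ok:
                feasible.append((subset, growth, scfa))
                if min_card is None:
                    min_card = size
                if size == min_card:
                    minimal.append(subset)
    if min_card is None:
        min_card = -1  # nothing feasible (cannot happen if the full set passes)
    return OracleReport(feasible, minimal, min_card, tested)


def verify_solution(
    comm: CommunityModel,
    sol: MinimalMicrobiome,
    spec: FunctionalitySpec,
    targets: Targets,
    tol: float = 1e-6,
) -> dict[str, float]:
    """Independently re-check a solution's fluxes against the constraints.

    Assembles the dense system from the raw member models and verifies mass
    balance, bounds (zero for excluded members), coupling rows and the two
    retention thresholds at the reported fluxes. Returns the residuals;
    raises ``AssertionError`` if any exceeds ``tol``.
    """
    system = _DenseSystem(comm)
    v = np.array([sol.fluxes.get(name, 0.0) for name in system.names])
    residuals: dict[str, float] = {}
    residuals["mass_balance"] = float(np.abs(system.A_eq @ v).max())
    bounds = system.bounds_for_subset(frozenset(sol.members))
    residuals["bounds"] = float(
        max(np.max(bounds[:, 0] - v, initial=0.0), np.max(v - bounds[:, 1], initial=0.0))
    )
    if len(system.b_ub):
        residuals["coupling"] = float(np.max(system.A_ub @ v - system.b_ub, initial=0.0))
    else:
        residuals["coupling"] = 0.0
    scfa = float(system.scfa_objective(spec) @ v)
    residuals["scfa_threshold"] = max(0.0, targets.scfa_threshold - THRESHOLD_SLACK - scfa)
    if targets.growth_constraint_mode == "community":
        growth = float(system.biomass_objective(frozenset(sol.members)) @ v)
        residuals["growth_threshold"] = max(
            0.0, (targets.growth_threshold - THRESHOLD_SLACK - growth)
            if targets.growth_threshold > THRESHOLD_SLACK else 0.0
        )
    else:
        worst = 0.0
        for k, colk in system.biomass_col.items():
            sp = system.members[k - 1]
            if sp in sol.members:
                floor = targets.gr_frac * targets.theta_k.get(sp, 0.0)
                worst = max(worst, floor - THRESHOLD_SLACK - v[colk])
        residuals["growth_threshold"] = max(0.0, worst)
    bad = {k: r for k, r in residuals.items() if r > tol}
    if bad:
        raise AssertionError(f"solution violates constraints beyond {tol}: {bad}")
    return residuals
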