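"""The three-step minimal-microbiome workflow.

Step 1 — joint FBA: maximise the sum of member biomass fluxes of the full
community on its diet; record the community growth rate and each member's
growth rate θ^k.

Step 2 — SCFA flux variability: maximise a weighted sum of community SCFA
exchange fluxes (acetate, butyrate, propionate by default) while holding
each member's growth at ≥ gr_opt_frac·θ^k; record the maximum ϑ_SCFA.

Step 3 — minimisation: shrink the community by sequential deletion (a
species is removed when the remaining community still meets the growth and
SCFA retention thresholds), then solve a MILP minimising the number of
members, with binary membership variables gating each member's fluxes and
the thresholds

    Σ_w v_SCFA ≥ scfa_frac · ϑ_SCFA        (functionality retention)
    Σ_k v_biomass^k ≥ gr_frac · Σ_k θ^k    (growth retention, default mode)

Multiple minimal communities usually exist; integer cuts enumerate
alternatives, and repeated runs with fresh random deletion sequences
explore sequence-dependent optima.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from minmicrobiome.community import (
    CommunityModel,
    add_coupling,
    apply_diet,
    build_community,
    delete_species,
    restore_species,
    DEFAULT_COUPLING_C,
    DEFAULT_COUPLING_U,
)
from minmicrobiome.model_io import Diet, MicrobeModel
from minmicrobiome.solve import FEASIBILITY_TOL, SolveResult, community_lp, solve_lp, solve_milp

logger = logging.getLogger(__name__)

#: slack used when comparing an achieved flux against a threshold, to avoid
#: boundary flapping at LP tolerance
THRESHOLD_SLACK = 1e-9

DEFAULT_SCFA_EXCHANGES = ("EX_ac(e)", "EX_but(e)", "EX_ppa(e)")


class InfeasibleCommunityError(RuntimeError):
    """A solve that should be feasible was not (malformed constraints)."""


@dataclass(frozen=True)
class FunctionalitySpec:
    """Which SCFA objective to use.

    ``constraint_id`` 1 maximises the weighted sum of all three SCFA
    exchanges (weights default 1:1:1); 2, 3 and 4 single out acetate,
    butyrate and propionate respectively (equivalent to weight triples
    (1,0,0), (0,1,0), (0,0,1)).
    """

    constraint_id: int = 1
    scfa_exchange_ids: tuple[str, str, str] = DEFAULT_SCFA_EXCHANGES
    weights: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.constraint_id not in {1, 2, 3, 4}:
            raise ValueError(f"constraint_id must be 1-4, got {self.constraint_id}")
        if len(self.scfa_exchange_ids) != 3:
            raise ValueError("exactly three SCFA exchange ids are supported per run")
        if self.weights is not None:
            if len(self.weights) != 3 or any(w < 0 for w in self.weights):
                raise ValueError("weights must be three nonnegative reals")

    @property
    def effective_weights(self) -> tuple[float, float, float]:
        if self.constraint_id == 1:
            return tuple(self.weights) if self.weights is not None else (1.0, 1.0, 1.0)
        unit = {2: (1.0, 0.0, 0.0), 3: (0.0, 1.0, 0.0), 4: (0.0, 0.0, 1.0)}
        return unit[self.constraint_id]

    def objective_coeffs(self, comm: CommunityModel) -> dict[str, float]:
        """Community-exchange objective coefficients (absent exchanges warn)."""
        coeffs: dict[str, float] = {}
        for ex_id, w in zip(self.scfa_exchange_ids, self.effective_weights):
            if w == 0:
                continue
            if ex_id not in comm.community_exchange:
                warnings.warn(f"community has no exchange {ex_id!r}; weight ignored", stacklevel=2)
                continue
            coeffs[ex_id] = coeffs.get(ex_id, 0.0) + w
        return coeffs


@dataclass(frozen=True)
class Params:
    """Algorithm parameters (defaults follow the method's standard setting)."""

    gr_opt_frac: float = 0.99
    gr_frac: float = 0.8
    scfa_frac: float = 0.8
    milp_size: int = 8
    deletion_sequence: list[str] | None = None
    seed: int = 0
    growth_constraint_mode: str = "community"  # or "per_species"
    iterations: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.gr_opt_frac <= 1:
            raise ValueError("gr_opt_frac must be in (0, 1]")
        if not 0 <= self.gr_frac <= 1 or not 0 <= self.scfa_frac <= 1:
            raise ValueError("gr_frac and scfa_frac must be in [0, 1]")
        if self.milp_size < 1:
            raise ValueError("milp_size must be >= 1")
        if self.growth_constraint_mode not in {"community", "per_species"}:
            raise ValueError("growth_constraint_mode must be 'community' or 'per_species'")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class Targets:
    """Thresholds derived from Steps 1-2."""

    theta_k: dict[str, float]  # species id -> joint-FBA growth rate (1/h)
    scfa_max: float  # mmol/gDW-h
    gr_frac: float
    scfa_frac: float
    growth_constraint_mode: str = "community"

    @property
    def theta_total(self) -> float:
        return float(sum(self.theta_k.values()))

    @property
    def growth_threshold(self) -> float:
        return self.gr_frac * self.theta_total

    @property
    def scfa_threshold(self) -> float:
        return self.scfa_frac * self.scfa_max


@dataclass
class MinimalMicrobiome:
    """A solution: a species subset with its achieved fluxes."""

    members: frozenset[str]
    growth: float
    scfa_flux: float
    per_species_growth: dict[str, float]
    all_species: list[str]
    provenance: dict = field(default_factory=dict)
    fluxes: dict[str, float] = field(default_factory=dict)


@dataclass
class ReductionTrace:
    steps: list[tuple[str, str, str]] = field(default_factory=list)  # (species, action, reason)
    final_active: list[str] = field(default_factory=list)

    @property
    def n_deleted(self) -> int:
        return sum(1 for _, action, _ in self.steps if action == "deleted")


# ---------------------------------------------------------------------------
# Steps 1 and 2
# ---------------------------------------------------------------------------

def _biomass_objective(comm: CommunityModel) -> dict[str, float]:
    return {comm.biomass[k]: 1.0 for k in comm.active_members()}


def joint_fba(comm: CommunityModel, backend: str = "highs") -> SolveResult:
    """Maximise the sum of active members' biomass fluxes (Step 1)."""
    p = community_lp(comm, _biomass_objective(comm), "max")
    res = solve_lp(p, backend=backend)
    if not res.optimal:
        raise InfeasibleCommunityError(
            f"community cannot grow on this diet (joint FBA {res.status}: {res.message})"
        )
    return res


def member_growths(comm: CommunityModel, res: SolveResult) -> dict[str, float]:
    """Extract θ^k for every active member from a joint-FBA solution."""
    return {
        comm.members[k - 1]: res.fluxes[comm.biomass[k]]
        for k in comm.active_members()
    }


def scfa_fva_max(
    comm: CommunityModel,
    spec: FunctionalitySpec,
    theta_k: dict[str, float],
    gr_opt_frac: float = 0.99,
    backend: str = "highs",
) -> tuple[float, dict[str, float]]:
    """Maximise the weighted SCFA exchange sum at near-optimal growth (Step 2).

    Each active member's biomass flux is bounded below by
    ``gr_opt_frac·θ^k``. Returns ``(ϑ_SCFA, per-exchange fluxes)``; the
    individual fluxes may be negative (uptake is not forbidden).
    """
    coeffs = spec.objective_coeffs(comm)
    p = community_lp(comm, coeffs, "max")
    for k in comm.active_members():
        sp = comm.members[k - 1]
        p.add_ge({comm.biomass[k]: 1.0}, gr_opt_frac * theta_k[sp])
    if not coeffs:  # all weights zero or no matching exchanges
        return 0.0, {ex: 0.0 for ex in spec.scfa_exchange_ids}
    res = solve_lp(p, backend=backend)
    if not res.optimal:
        raise InfeasibleCommunityError(f"SCFA FVA {res.status}: {res.message}")
    triple = {
        ex: res.fluxes.get(ex, 0.0) for ex in spec.scfa_exchange_ids
    }
    return res.objective_value, triple


def build_targets(theta_k: dict[str, float], scfa_max: float, params: Params) -> Targets:
    """Bundle Step-1/2 outputs with the retention fractions."""
    return Targets(
        theta_k=dict(theta_k),
        scfa_max=float(scfa_max),
        gr_frac=params.gr_frac,
        scfa_frac=params.scfa_frac,
        growth_constraint_mode=params.growth_constraint_mode,
    )


# ---------------------------------------------------------------------------
# Step 3: sequential deletion
# ---------------------------------------------------------------------------

def _growth_rows(p, comm: CommunityModel, targets: Targets) -> None:
    """Impose the growth retention threshold on a (pure-LP) problem."""
    if targets.growth_constraint_mode == "community":
        coeffs = {comm.biomass[k]: 1.0 for k in comm.active_members()}
        if coeffs:
            p.add_ge(coeffs, targets.growth_threshold)
    else:
        for k in comm.active_members():
            sp = comm.members[k - 1]
            p.add_ge({comm.biomass[k]: 1.0}, targets.gr_frac * targets.theta_k.get(sp, 0.0))


def check_reduced_feasible(
    comm: CommunityModel,
    spec: FunctionalitySpec,
    targets: Targets,
    backend: str = "highs",
) -> bool:
    """Does this (possibly reduced) community still meet the thresholds?

    Two LPs: a growth check (FBA) and a SCFA check (FVA at the growth
    threshold), mirroring the per-deletion cost of the reduction loop.
    """
    if comm.n_active == 0:
        return targets.growth_threshold <= THRESHOLD_SLACK and targets.scfa_threshold <= THRESHOLD_SLACK
    # (a) growth
    p = community_lp(comm, _biomass_objective(comm), "max")
    if targets.growth_constraint_mode == "per_species":
        _growth_rows(p, comm, targets)  # feasibility of all per-species floors
        res = solve_lp(p, backend=backend)
        if not res.optimal:
            return False
    else:
        res = solve_lp(p, backend=backend)
        if not res.optimal or res.objective_value < targets.growth_threshold - THRESHOLD_SLACK:
            return False
    # (b) SCFA at the growth threshold
    coeffs = spec.objective_coeffs(comm)
    if targets.scfa_threshold <= THRESHOLD_SLACK:
        return True
    if not coeffs:
        return False
    p = community_lp(comm, coeffs, "max")
    _growth_rows(p, comm, targets)
    res = solve_lp(p, backend=backend)
    return res.optimal and res.objective_value >= targets.scfa_threshold - THRESHOLD_SLACK


def sequential_reduce(
    comm: CommunityModel,
    spec: FunctionalitySpec,
    targets: Targets,
    params: Params,
    backend: str = "highs",
) -> ReductionTrace:
    """Delete species one by one while the thresholds stay satisfiable.

    The deletion sequence is the user's, or a random permutation drawn from
    ``params.seed``. The sequence is swept repeatedly until the community is
    at most ``milp_size`` members or a full pass deletes nothing. The
    community is modified in place (deletions are reversible via
    :func:`restore_species`).
    """
    if params.deletion_sequence is not None:
        sequence = [s for s in params.deletion_sequence]
        unknown = [s for s in sequence if s not in comm.members]
        if unknown:
            raise ValueError(f"deletion sequence names unknown species {unknown}")
    else:
        rng = np.random.default_rng(params.seed)
        sequence = [comm.members[i] for i in rng.permutation(len(comm.members))]
    trace = ReductionTrace()
    while comm.n_active > params.milp_size:
        deleted_this_pass = 0
        for sp in sequence:
            if comm.n_active <= params.milp_size:
                break
            k = comm.member_index(sp)
            if not comm.active[k - 1]:
                continue
            if comm.n_active == 1:
                break
            delete_species(comm, sp)
            if check_reduced_feasible(comm, spec, targets, backend=backend):
                trace.steps.append((sp, "deleted", "thresholds still satisfiable"))
                deleted_this_pass += 1
                logger.info("deleted %s (community now %d members)", sp, comm.n_active)
            else:
                restore_species(comm, sp)
                trace.steps.append((sp, "kept", "deletion breaks thresholds"))
                logger.info("kept %s (deletion breaks thresholds)", sp)
        if deleted_this_pass == 0:
            break
    trace.final_active = [comm.members[k - 1] for k in comm.active_members()]
    return trace


# ---------------------------------------------------------------------------
# Step 3: membership MILP
# ---------------------------------------------------------------------------

def _membership_milp(
    comm: CommunityModel,
    spec: FunctionalitySpec,
    targets: Targets,
    gate_mode: str = "full",
):
    """Assemble the membership MILP over the community's active members.

    Binary X^k per active member. The biomass flux is always gated
    (LB·X ≤ v ≤ UB·X). Under the default ``full`` gate mode every reaction
    of member k is gated the same way so X^k = 0 excludes the member
    exactly; ``coupling_only`` gates only the biomass and relies on the
    coupling rows, which leaves |v| ≤ u leakage for excluded members.
    """
    if gate_mode not in {"full", "coupling_only"}:
        raise ValueError(f"unknown gate mode {gate_mode!r}")
    p = community_lp(comm, {}, "min")
    x_name = {}
    for k in comm.active_members():
        sp = comm.members[k - 1]
        xn = f"X[{sp}]"
        p.add_variable(xn, 0.0, 1.0, binary=True)
        x_name[k] = xn
        gated = comm.member_reactions(k) if gate_mode == "full" else [comm.rxn_index(comm.biomass[k])]
        bio_j = comm.rxn_index(comm.biomass[k])
        if gate_mode == "full":
            cols = gated
        else:
            cols = [bio_j]
        for j in cols:
            rid = comm.reactions[j]
            lbj, ubj = comm.lb[j], comm.ub[j]
            if ubj != 0:
                p.add_le({rid: 1.0, xn: -ubj}, 0.0)  # v ≤ UB·X
            else:
                p.add_le({rid: 1.0}, 0.0)
            if lbj != 0:
                p.add_ge({rid: 1.0, xn: -lbj}, 0.0)  # v ≥ LB·X
            else:
                p.add_ge({rid: 1.0}, 0.0)
    # functionality threshold
    coeffs = spec.objective_coeffs(comm)
    if targets.scfa_threshold > THRESHOLD_SLACK:
        if not coeffs:
            raise InfeasibleCommunityError(
                "SCFA threshold is positive but no weighted SCFA exchange exists"
            )
        p.add_ge(coeffs, targets.scfa_threshold - THRESHOLD_SLACK)
    # growth threshold
    if targets.growth_constraint_mode == "community":
        bio = {comm.biomass[k]: 1.0 for k in comm.active_members()}
        if bio and targets.growth_threshold > THRESHOLD_SLACK:
            p.add_ge(bio, targets.growth_threshold - THRESHOLD_SLACK)
    else:
        # membership-gated per-species floor: v_bio ≥ gr_frac·θ^k·X^k
        for k in comm.active_members():
            sp = comm.members[k - 1]
            floor = targets.gr_frac * targets.theta_k.get(sp, 0.0)
            if floor > THRESHOLD_SLACK:
                p.add_ge({comm.biomass[k]: 1.0, x_name[k]: -floor}, -THRESHOLD_SLACK)
    p.set_objective({xn: 1.0 for xn in x_name.values()}, "min")
    return p, x_name


def _solution_from_result(
    comm: CommunityModel,
    spec: FunctionalitySpec,
    res: SolveResult,
    x_name: dict[int, str],
    provenance: dict,
) -> MinimalMicrobiome:
    members = frozenset(
        comm.members[k - 1] for k, xn in x_name.items() if res.membership.get(xn, 0) == 1
    )
    per_growth = {
        comm.members[k - 1]: res.fluxes[comm.biomass[k]] for k in x_name
    }
    growth = float(sum(per_growth.values()))
    coeffs = spec.objective_coeffs(comm)
    scfa = float(sum(w * res.fluxes.get(ex, 0.0) for ex, w in coeffs.items()))
    return MinimalMicrobiome(
        members=members,
        growth=growth,
        scfa_flux=scfa,
        per_species_growth=per_growth,
        all_species=list(comm.members),
        provenance=provenance,
        fluxes=dict(res.fluxes),
    )


def minimize_membership(
    comm: CommunityModel,
    spec: FunctionalitySpec,
    targets: Targets,
    gate_mode: str = "full",
    backend: str = "highs",
    provenance: dict | None = None,
) -> MinimalMicrobiome:
    """Solve the membership MILP: fewest members meeting the thresholds."""
    p, x_name = _membership_milp(comm, spec, targets, gate_mode=gate_mode)
    res = solve_milp(p, backend=backend)
    if not res.optimal:
        raise InfeasibleCommunityError(
            f"no sub-community satisfies the functionality constraints ({res.status})"
        )
    sol = _solution_from_result(comm, spec, res, x_name, dict(provenance or {}))
    sol.provenance.setdefault("solver_status", res.status)
    sol.provenance["milp_objective"] = res.objective_value
    if not sol.members:
        warnings.warn(
            "thresholds are degenerate (zero); the empty community is optimal", stacklevel=2
        )
    logger.info("MILP optimum %d members: %s", len(sol.members), sorted(sol.members))
    return sol


def enumerate_minimal(
    comm: CommunityModel,
    spec: FunctionalitySpec,
    targets: Targets,
    max_solutions: int = 10,
    same_cardinality_only: bool = True,
    gate_mode: str = "full",
    backend: str = "highs",
) -> list[MinimalMicrobiome]:
    """Enumerate alternative optima with integer cuts.

    After each solution S, the cut Σ_{k∈S} X^k ≤ |S|−1 excludes every
    support that contains all of S. Stops at ``max_solutions``, at
    infeasibility, or — with ``same_cardinality_only`` — when the optimum
    grows beyond the first solution's cardinality.
    """
    if max_solutions < 1:
        raise ValueError("max_solutions must be >= 1")
    p, x_name = _membership_milp(comm, spec, targets, gate_mode=gate_mode)
    solutions: list[MinimalMicrobiome] = []
    first_card: int | None = None
    while len(solutions) < max_solutions:
        res = solve_milp(p, backend=backend)
        if not res.optimal:
            break
        card = int(round(res.objective_value))
        if first_card is None:
            first_card = card
        elif same_cardinality_only and card > first_card:
            break
        sol = _solution_from_result(
            comm, spec, res, x_name, {"integer_cut_index": len(solutions)}
        )
        sol.provenance["milp_objective"] = res.objective_value
        solutions.append(sol)
        support = [xn for xn in x_name.values() if res.membership.get(xn, 0) == 1]
        if not support:  # degenerate empty optimum: nothing to cut
            break
        p.add_le({xn: 1.0 for xn in support}, len(support) - 1)
    return solutions


def max_scfa_of_minimal(
    comm: CommunityModel,
    members: "frozenset[str] | set[str] | list[str]",
    spec: FunctionalitySpec,
    targets: Targets,
    backend: str = "highs",
) -> float:
    """Maximum weighted SCFA flux achievable by a given support.

    All non-members are deleted, the growth and SCFA retention thresholds
    stay imposed, and the weighted SCFA sum is maximised (an LP).
    """
    members = set(members)
    unknown = members - set(comm.members)
    if unknown:
        raise ValueError(f"unknown species {sorted(unknown)}")
    sub = comm.copy()
    for sp in sub.members:
        k = sub.member_index(sp)
        if sp not in members and sub.active[k - 1]:
            if sub.n_active == 1:
                raise InfeasibleCommunityError("support excludes every active member")
            delete_species(sub, sp)
    coeffs = spec.objective_coeffs(sub)
    p = community_lp(sub, coeffs, "max")
    _growth_rows(p, sub, targets)
    if targets.scfa_threshold > THRESHOLD_SLACK and coeffs:
        p.add_ge(coeffs, targets.scfa_threshold - THRESHOLD_SLACK)
    res = solve_lp(p, backend=backend)
    if not res.optimal:
        raise InfeasibleCommunityError(f"support is infeasible at the thresholds ({res.status})")
    return res.objective_value


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def prepare_community(
    models: list[MicrobeModel],
    diet: Diet,
    coupling_c: float = DEFAULT_COUPLING_C,
    coupling_u: float = DEFAULT_COUPLING_U,
    diet_policy: str = "closed",
) -> CommunityModel:
    """Build + diet + coupling in the standard order."""
    comm = build_community(models)
    apply_diet(comm, diet, policy=diet_policy)
    add_coupling(comm, c=coupling_c, u=coupling_u)
    return comm


def find_minimal_microbiomes(
    models: list[MicrobeModel],
    diet: Diet,
    spec: FunctionalitySpec,
    params: Params,
    coupling_c: float = DEFAULT_COUPLING_C,
    coupling_u: float = DEFAULT_COUPLING_U,
    diet_policy: str = "closed",
    enumerate_per_iteration: int = 1,
    gate_mode: str = "full",
    backend: str = "highs",
) -> list[MinimalMicrobiome]:
    """Run the full three-step pipeline and return deduplicated solutions.

    Each iteration draws a fresh deletion sequence (seed ``params.seed + i``)
    so different sequence-dependent optima can surface; solutions are
    deduplicated on membership, keeping the first provenance.
    """
    comm = prepare_community(models, diet, coupling_c, coupling_u, diet_policy)
    logger.info("stage: joint FBA (%d members)", len(comm.members))
    fba = joint_fba(comm, backend=backend)
    theta_k = member_growths(comm, fba)
    logger.info("community growth %.6g", fba.objective_value)
    logger.info("stage: SCFA FVA (constraint %d)", spec.constraint_id)
    scfa_max, triple = scfa_fva_max(comm, spec, theta_k, params.gr_opt_frac, backend=backend)
    logger.info("max weighted SCFA %.6g %s", scfa_max, triple)
    targets = build_targets(theta_k, scfa_max, params)

    solutions: list[MinimalMicrobiome] = []
    seen: set[frozenset[str]] = set()
    for it in range(params.iterations):
        it_seed = params.seed + it
        it_params = replace(params, seed=it_seed)
        work = comm.copy()
        logger.info("stage: sequential reduction (iteration %d, seed %d)", it + 1, it_seed)
        trace = sequential_reduce(work, spec, targets, it_params, backend=backend)
        logger.info("reduced to %d members: %s", work.n_active, trace.final_active)
        provenance = {
            "iteration": it + 1,
            "seed": it_seed,
            "deletion_sequence": [s for s, a, _ in trace.steps],
            "deleted": [s for s, a, _ in trace.steps if a == "deleted"],
            "final_active": trace.final_active,
        }
        if enumerate_per_iteration > 1:
            found = enumerate_minimal(
                work, spec, targets, max_solutions=enumerate_per_iteration,
                gate_mode=gate_mode, backend=backend,
            )
            for sol in found:
                sol.provenance.update(provenance)
        else:
            found = [
                minimize_membership(
                    work, spec, targets, gate_mode=gate_mode, backend=backend,
                    provenance=provenance,
                )
            ]
        for sol in found:
            if sol.members not in seen:
                seen.add(sol.members)
                solutions.append(sol)
    return solutions
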