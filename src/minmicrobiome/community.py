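"""Compartmentalised community models.

Each member species becomes a compartment: its metabolites and reactions are
suffixed ``_org<k>`` (1-based, the COBRA community convention). Member
exchange reactions are rewired to move the exchanged metabolite between the
member and a shared pool compartment (metabolite ids suffixed ``[u]``), and
one community-level exchange reaction per pooled metabolite connects the
pool to the environment. The pool mass balance makes the community exchange
flux of every metabolite equal the sum of the members' exchange fluxes,
which is what enables cross-feeding.

Coupling constraints tie every non-biomass member flux to that member's
biomass flux (|v_j| − c·v_biomass ≤ u), so a member that does not grow
cannot run its metabolism; deletion of a member zeroes all its flux bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from minmicrobiome.model_io import Diet, MicrobeModel, DEFAULT_OPEN_BOUND

#: default coupling coefficient and threshold (the community-coupling
#: convention commonly used with AGORA-style models)
DEFAULT_COUPLING_C = 400.0
DEFAULT_COUPLING_U = 0.01


@dataclass
class CouplingRow:
    """One coupling inequality: ``sign·v_rxn − c·v_biomass ≤ u``."""

    rxn: str
    species: int  # 1-based member index
    c: float
    u: float
    sign: int  # +1 or -1; both directions of a reversible flux are coupled


@dataclass
class CommunityModel:
    members: list[str]
    source_models: list[MicrobeModel]
    metabolites: list[str]
    reactions: list[str]
    S: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    biomass: dict[int, str]  # member index (1-based) -> tagged biomass rxn id
    rxn_species: np.ndarray  # per-reaction member index; 0 = community level
    member_exchange: dict[int, list[tuple[str, str]]]  # k -> [(tagged ex rxn, pool met)]
    community_exchange: dict[str, str]  # community EX rxn id -> pool met id
    active: np.ndarray  # bool per member (index k-1)
    couplings: list[CouplingRow] = field(default_factory=list)
    coupling_params: tuple[float, float] | None = None
    diet: Diet | None = None
    diet_policy: str = "closed"
    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False)
    _archived_bounds: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict, repr=False)

    # -- lookups ---------------------------------------------------------
    def rxn_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def tag(self, k: int) -> str:
        return f"_org{k}"

    def member_index(self, species: "int | str") -> int:
        """Resolve a species id or 1-based index to the 1-based index."""
        if isinstance(species, str):
            return self.members.index(species) + 1
        k = int(species)
        if not 1 <= k <= len(self.members):
            raise IndexError(f"species index {k} out of range 1..{len(self.members)}")
        return k

    def member_reactions(self, k: int) -> np.ndarray:
        """Column indices of all reactions belonging to member k."""
        return np.nonzero(self.rxn_species == k)[0]

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def active_members(self) -> list[int]:
        return [k for k in range(1, len(self.members) + 1) if self.active[k - 1]]

    def copy(self) -> "CommunityModel":
        out = CommunityModel(
            members=list(self.members),
            source_models=self.source_models,  # read-only, shared
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            S=self.S,
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            biomass=dict(self.biomass),
            rxn_species=self.rxn_species,
            member_exchange={k: list(v) for k, v in self.member_exchange.items()},
            community_exchange=dict(self.community_exchange),
            active=self.active.copy(),
            couplings=list(self.couplings),
            coupling_params=self.coupling_params,
            diet=self.diet,
            diet_policy=self.diet_policy,
        )
        out._rxn_index = self._rxn_index
        out._archived_bounds = {k: (l.copy(), u.copy()) for k, (l, u) in self._archived_bounds.items()}
        return out


def _pool_met(met_id: str) -> str:
    return f"{met_id}[u]"


def build_community(models: list[MicrobeModel], open_bound: float = DEFAULT_OPEN_BOUND) -> CommunityModel:
    """Merge member models into one compartmentalised community model.

    Member internals keep their bounds; member exchange reactions become
    transfers into the shared pool; community exchange reactions (one per
    pooled metabolite, named after the member exchange id without the tag)
    start fully open at ±``open_bound`` until a diet is applied.
    """
    if not models:
        raise ValueError("need at least one member model")
    ids = [m.id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate species ids: {sorted(ids)}")
    for m in models:
        m.validate()

    metabolites: list[str] = []
    reactions: list[str] = []
    lb: list[float] = []
    ub: list[float] = []
    rxn_species: list[int] = []
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    met_index: dict[str, int] = {}
    biomass: dict[int, str] = {}
    member_exchange: dict[int, list[tuple[str, str]]] = {}
    community_exchange: dict[str, str] = {}

    def add_met(mid: str) -> int:
        if mid not in met_index:
            met_index[mid] = len(metabolites)
            metabolites.append(mid)
        return met_index[mid]

    for k, model in enumerate(models, start=1):
        tag = f"_org{k}"
        exchange_ids = {r for r, _ in model.exchange_rxns}
        ex_met = dict(model.exchange_rxns)
        coo = model.S.tocoo()
        col_entries: dict[int, list[tuple[int, float]]] = {}
        for i, j, v in zip(coo.row, coo.col, coo.data):
            col_entries.setdefault(j, []).append((i, v))
        member_exchange[k] = []
        for j, rid in enumerate(model.reactions):
            tagged = rid + tag
            col = len(reactions)
            reactions.append(tagged)
            lb.append(float(model.lb[j]))
            ub.append(float(model.ub[j]))
            rxn_species.append(k)
            for i, v in col_entries.get(j, []):
                rows.append(add_met(model.metabolites[i] + tag))
                cols.append(col)
                vals.append(float(v))
            if rid == model.biomass_rxn:
                biomass[k] = tagged
            if rid in exchange_ids:
                pool = _pool_met(ex_met[rid])
                rows.append(add_met(pool))
                cols.append(col)
                vals.append(1.0)  # secretion (+v) feeds the pool
                member_exchange[k].append((tagged, pool))
                if rid not in community_exchange:
                    community_exchange[rid] = pool

    # community exchange reactions: pool -> environment, drain coefficient -1
    for ex_id, pool in community_exchange.items():
        col = len(reactions)
        reactions.append(ex_id)
        lb.append(-open_bound)
        ub.append(open_bound)
        rxn_species.append(0)
        rows.append(met_index[pool])
        cols.append(col)
        vals.append(-1.0)

    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(metabolites), len(reactions))
    )
    comm = CommunityModel(
        members=ids,
        source_models=list(models),
        metabolites=metabolites,
        reactions=reactions,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        biomass=biomass,
        rxn_species=np.array(rxn_species),
        member_exchange=member_exchange,
        community_exchange=community_exchange,
        active=np.ones(len(ids), dtype=bool),
    )
    comm._rxn_index = {r: i for i, r in enumerate(reactions)}
    return comm


def add_coupling(
    comm: CommunityModel,
    c: float = DEFAULT_COUPLING_C,
    u: float = DEFAULT_COUPLING_U,
    include_exchanges: bool = True,
) -> CommunityModel:
    """Couple every non-biomass member reaction to its member's biomass.

    Adds two rows per reaction, ``v_j − c·v_bio ≤ u`` and
    ``−v_j − c·v_bio ≤ u``, so both directions of reversible fluxes are
    tied to growth. ``include_exchanges=False`` restricts coupling to
    internal (non pool-transfer) reactions.
    """
    if c <= 0:
        raise ValueError(f"coupling coefficient must be positive, got {c}")
    if u < 0:
        raise ValueError(f"coupling threshold must be nonnegative, got {u}")
    comm.couplings = []
    for k in range(1, len(comm.members) + 1):
        bio = comm.biomass[k]
        transfer = {r for r, _ in comm.member_exchange[k]}
        for j in comm.member_reactions(k):
            rid = comm.reactions[j]
            if rid == bio:
                continue
            if not include_exchanges and rid in transfer:
                continue
            comm.couplings.append(CouplingRow(rxn=rid, species=k, c=c, u=u, sign=+1))
            comm.couplings.append(CouplingRow(rxn=rid, species=k, c=c, u=u, sign=-1))
    comm.coupling_params = (c, u)
    return comm


def delete_species(comm: CommunityModel, species: "int | str") -> CommunityModel:
    """Delete a member: zero the bounds of all its reactions (reversibly)."""
    k = comm.member_index(species)
    if not comm.active[k - 1]:
        raise ValueError(f"species {comm.members[k - 1]!r} already deleted")
    if comm.n_active <= 1:
        raise ValueError("community must retain at least one member")
    idx = comm.member_reactions(k)
    comm._archived_bounds[k] = (comm.lb[idx].copy(), comm.ub[idx].copy())
    comm.lb[idx] = 0.0
    comm.ub[idx] = 0.0
    comm.active[k - 1] = False
    return comm


def restore_species(comm: CommunityModel, species: "int | str") -> CommunityModel:
    """Undo :func:`delete_species`; bounds are restored bit-identically."""
    k = comm.member_index(species)
    if comm.active[k - 1]:
        raise ValueError(f"species {comm.members[k - 1]!r} is not deleted")
    idx = comm.member_reactions(k)
    lb, ub = comm._archived_bounds.pop(k)
    comm.lb[idx] = lb
    comm.ub[idx] = ub
    comm.active[k - 1] = True
    return comm


def apply_diet(comm: CommunityModel, diet: Diet, policy: str = "closed") -> CommunityModel:
    """Set community exchange bounds from a diet.

    Exchanges listed in the diet get the diet bounds. Unlisted community
    exchanges keep their upper bound; under the default ``closed`` policy
    their lower bound is set to 0 (nothing supplied by the environment),
    under ``open`` they are left as built. Diet entries naming exchanges the
    community does not have are warnings, since diets are generic tables.
    """
    if policy not in {"closed", "open"}:
        raise ValueError(f"unknown diet policy {policy!r}")
    unknown = [ex for ex in diet.bounds if ex not in comm.community_exchange]
    if unknown:
        warnings.warn(f"diet {diet.name!r}: no community exchange for {unknown}", stacklevel=2)
    for ex_id in comm.community_exchange:
        j = comm.rxn_index(ex_id)
        if ex_id in diet.bounds:
            comm.lb[j], comm.ub[j] = diet.bounds[ex_id]
        elif policy == "closed":
            comm.lb[j] = 0.0
    comm.diet = diet
    comm.diet_policy = policy
    return comm
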