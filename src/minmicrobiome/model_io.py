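"""Read and write species models, diets and results.

Species models are ordinary constraint-based reconstructions (SBML L3/FBC or
COBRA JSON, AGORA-style naming). They are parsed with cobrapy and converted
to a light matrix container, :class:`MicrobeModel`, which is what the rest of
the package operates on.

Conventions (standard COBRA):

* exchange flux > 0 means secretion, < 0 means uptake;
* exchange reactions are identified by the prefix ``EX_`` and must drain a
  single extracellular metabolite with coefficient −1;
* the biomass reaction is found by a configurable pattern, by default any
  reaction id containing "biomass" (case-insensitive) — AGORA models carry
  exactly one such reaction.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from scipy import sparse

if TYPE_CHECKING:  # avoid circular import at runtime
    from minmicrobiome.workflow import MinimalMicrobiome

DEFAULT_OPEN_BOUND = 1000.0
EXCHANGE_PREFIX = "EX_"
BIOMASS_PATTERN = "biomass"


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed or violates invariants."""


class AmbiguousBiomassError(ValueError):
    """Raised when zero or several reactions match the biomass pattern."""


class DietParseError(ValueError):
    """Raised for malformed diet tables (carries the offending line number)."""


@dataclass
class MicrobeModel:
    """One species' stoichiometric network.

    Attributes
    ----------
    id : str
        Species identifier.
    metabolites, reactions : list of str
        Row and column identities of ``S`` (metabolite ids carry their
        compartment tag, e.g. ``glc(e)``).
    S : scipy.sparse.csc_matrix
        Stoichiometric matrix, metabolites × reactions.
    lb, ub : numpy.ndarray
        Per-reaction flux bounds in mmol/gDW-h.
    biomass_rxn : str
        The single biomass reaction id.
    exchange_rxns : list of (str, str)
        ``(reaction id, exchanged metabolite id)`` pairs.
    """

    id: str
    metabolites: list[str]
    reactions: list[str]
    S: sparse.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    biomass_rxn: str
    exchange_rxns: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.S = sparse.csc_matrix(self.S)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ModelFormatError`` if violated."""
        n_met, n_rxn = self.S.shape
        if n_met != len(self.metabolites) or n_rxn != len(self.reactions):
            raise ModelFormatError(f"{self.id}: S shape {self.S.shape} does not match id lists")
        if self.biomass_rxn not in self.reactions:
            raise ModelFormatError(f"{self.id}: biomass reaction {self.biomass_rxn!r} not in reactions")
        if len(self.lb) != n_rxn or len(self.ub) != n_rxn:
            raise ModelFormatError(f"{self.id}: bound vectors do not match reaction count")
        if np.any(self.lb > self.ub):
            bad = [self.reactions[j] for j in np.nonzero(self.lb > self.ub)[0]]
            raise ModelFormatError(f"{self.id}: lb > ub for {bad}")
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        csc = self.S.tocsc()
        for rxn_id, met_id in self.exchange_rxns:
            if rxn_id not in self.reactions:
                raise ModelFormatError(f"{self.id}: exchange {rxn_id!r} not in reactions")
            j = self.reactions.index(rxn_id)
            col = csc.getcol(j)
            if col.nnz != 1:
                raise ModelFormatError(
                    f"{self.id}: exchange {rxn_id!r} must have exactly one stoichiometric entry"
                )
            i = col.indices[0]
            if i != met_index[met_id] or not np.isclose(col.data[0], -1.0):
                raise ModelFormatError(
                    f"{self.id}: exchange {rxn_id!r} must carry coefficient -1 for {met_id!r}"
                )

    def reaction_index(self, rxn_id: str) -> int:
        return self.reactions.index(rxn_id)

    def copy(self) -> "MicrobeModel":
        return MicrobeModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            biomass_rxn=self.biomass_rxn,
            exchange_rxns=list(self.exchange_rxns),
        )


@dataclass
class Diet:
    """Community exchange bounds: map exchange-reaction id → (lb, ub).

    Uptake is encoded as a negative lower bound (lb = −1 makes one unit of
    the metabolite available per gDW-h); lb = 0 removes it from the diet.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    name: str = "diet"

    def __post_init__(self) -> None:
        for ex_id, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise DietParseError(f"diet {self.name!r}: lb > ub for {ex_id!r} ({lb} > {ub})")


def _find_biomass(reaction_ids: list[str], pattern: str) -> str:
    rx = re.compile(pattern, re.IGNORECASE)
    hits = [r for r in reaction_ids if rx.search(r)]
    if len(hits) != 1:
        raise AmbiguousBiomassError(
            f"expected exactly one reaction matching {pattern!r}, found {len(hits)}: {hits}"
        )
    return hits[0]


def _from_cobra(model, model_id: str | None, biomass_pattern: str) -> MicrobeModel:
    from cobra.util.array import create_stoichiometric_matrix

    reactions = [r.id for r in model.reactions]
    metabolites = [m.id for m in model.metabolites]
    S = sparse.csc_matrix(create_stoichiometric_matrix(model, array_type="lil"))
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    biomass = _find_biomass(reactions, biomass_pattern)
    exchange = []
    for r in model.reactions:
        if r.id.startswith(EXCHANGE_PREFIX):
            if len(r.metabolites) != 1:
                raise ModelFormatError(f"exchange {r.id!r} touches {len(r.metabolites)} metabolites")
            met = next(iter(r.metabolites))
            exchange.append((r.id, met.id))
    out = MicrobeModel(
        id=model_id or model.id or "model",
        metabolites=metabolites,
        reactions=reactions,
        S=S,
        lb=lb,
        ub=ub,
        biomass_rxn=biomass,
        exchange_rxns=exchange,
    )
    out.validate()
    return out


def read_model(
    path: str | Path,
    format: str | None = None,
    biomass_pattern: str = BIOMASS_PATTERN,
    species_id: str | None = None,
) -> MicrobeModel:
    """Read an SBML or COBRA-JSON model file into a :class:`MicrobeModel`.

    ``format`` is inferred from the file suffix when not given
    (``.xml``/``.sbml`` → sbml, ``.json`` → json).
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    try:
        if format == "sbml":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = cobra.io.read_sbml_model(str(path))
        elif format == "json":
            model = cobra.io.load_json_model(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except AmbiguousBiomassError:
        raise
    except ValueError:
        raise
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return _from_cobra(model, species_id or path.stem, biomass_pattern)


_COMPARTMENT_RX = re.compile(r"[\[(](\w+)[\])]$")


def to_cobra(model: MicrobeModel):
    """Convert a :class:`MicrobeModel` to a ``cobra.Model`` (for writing)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = []
    for m in model.metabolites:
        match = _COMPARTMENT_RX.search(m)
        comp = match.group(1) if match else "c"
        mets.append(cobra.Metabolite(m, compartment=comp))
    cm.add_metabolites(mets)
    csc = model.S.tocsc()
    rxns = []
    for j, rid in enumerate(model.reactions):
        r = cobra.Reaction(rid, lower_bound=float(model.lb[j]), upper_bound=float(model.ub[j]))
        rxns.append(r)
    cm.add_reactions(rxns)
    for j, rid in enumerate(model.reactions):
        col = csc.getcol(j)
        cm.reactions.get_by_id(rid).add_metabolites(
            {cm.metabolites[i]: v for i, v in zip(col.indices, col.data)}
        )
    cm.objective = model.biomass_rxn
    return cm


def write_model(model: MicrobeModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as COBRA JSON or SBML L3/FBC."""
    import cobra.io

    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    cm = to_cobra(model)
    if format == "sbml":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra.io.write_sbml_model(cm, str(path))
    elif format == "json":
        cobra.io.save_json_model(cm, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def load_diet(path: str | Path, default_ub: float = DEFAULT_OPEN_BOUND, name: str | None = None) -> Diet:
    """Load a diet table: columns ``exchange_id``, ``lb``, optional ``ub``.

    Tab- or comma-separated; a header row is detected and skipped. A missing
    upper bound defaults to ``default_ub`` (1000 mmol/gDW-h, the COBRA open
    bound). An empty file yields an empty diet (community exchanges keep
    their defaults).
    """
    path = Path(path)
    bounds: dict[str, tuple[float, float]] = {}
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if ("\t" in sample or "," not in sample) else ","
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=1):
            row = [c.strip() for c in row if c.strip() != ""]
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1:
                try:
                    float(row[1])
                except (IndexError, ValueError):
                    continue  # header row
            if len(row) < 2 or len(row) > 3:
                raise DietParseError(f"{path}:{lineno}: expected 2-3 columns, got {len(row)}")
            ex_id = row[0]
            try:
                lb = float(row[1])
                ub = float(row[2]) if len(row) == 3 else default_ub
            except ValueError as exc:
                raise DietParseError(f"{path}:{lineno}: non-numeric bound in {row}") from exc
            if lb > ub:
                raise DietParseError(f"{path}:{lineno}: lb {lb} > ub {ub} for {ex_id!r}")
            bounds[ex_id] = (lb, ub)
    return Diet(bounds=bounds, name=name or path.stem)


def write_diet(diet: Diet, path: str | Path) -> None:
    """Write a diet as a 3-column TSV (exchange_id, lb, ub)."""
    with open(path, "w") as fh:
        fh.write("exchange_id\tlb\tub\n")
        for ex_id, (lb, ub) in sorted(diet.bounds.items()):
            fh.write(f"{ex_id}\t{lb:.17g}\t{ub:.17g}\n")


def write_result(results: "list[MinimalMicrobiome]", path: str | Path) -> None:
    """Serialise solutions: a presence/absence TSV plus a JSON sidecar.

    The TSV has one row per species (union over solutions' communities) and
    one column per solution, entries 0/1. The sidecar ``<path>.json`` records
    growth, SCFA fluxes and provenance per solution.
    """
    import pandas as pd

    if not results:
        raise ValueError("result list is empty")
    path = Path(path)
    species: list[str] = []
    for r in results:
        for s in r.all_species:
            if s not in species:
                species.append(s)
    cols = {}
    sidecar = {}
    for idx, r in enumerate(results, start=1):
        sol_id = f"solution_{idx}"
        cols[sol_id] = [1 if s in r.members else 0 for s in species]
        sidecar[sol_id] = {
            "members": sorted(r.members),
            "growth": r.growth,
            "scfa_flux": r.scfa_flux,
            "per_species_growth": r.per_species_growth,
            "provenance": r.provenance,
        }
    frame = pd.DataFrame(cols, index=species)
    frame.index.name = "species"
    frame.to_csv(path, sep="\t")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
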