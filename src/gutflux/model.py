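"""Stoichiometric data structures: taxon models, diet specs and the lumen-coupled community.

A :class:`TaxonModel` is one organism's metabolic network per gram dry weight
(gDW) of that organism.  Reaction fluxes are in mmol/gDW/h except the biomass
reaction, whose flux equals the growth rate in 1/h (the biomass reaction is
normalized so unit flux yields 1 g biomass).

A :class:`CommunityModel` embeds every taxon in a shared lumen compartment.
Each taxon keeps a private copy of its internal metabolites; its exchange
reactions move metabolites between the private compartment and the lumen.
Relative abundances ``a_i`` act as mass fractions: the lumen mass balance for
metabolite ``m`` reads

    sum_i a_i * v_i,ex(m) - v_env(m) = 0

where ``v_env(m)`` is the community-level environment exchange.  Positive
exchange flux means export out of the compartment; import is negative.  Diet
specifications set the maximum *uptake* (import magnitude) of each environment
exchange; secretion to the environment is unbounded.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCommunityError, InvalidModelError

logger = logging.getLogger(__name__)

#: default abundance cutoff below which a taxon is dropped from the community
ABUNDANCE_CUTOFF = 1e-4

#: large finite bound standing in for an unbounded flux
BIG = 1000.0

ROLE_INTERNAL = "internal"
ROLE_EXCHANGE = "exchange"
ROLE_TAXON_EXCHANGE = "taxon-exchange"
ROLE_LUMEN_EXCHANGE = "lumen-exchange"
ROLE_BIOMASS = "biomass"


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = "c"


@dataclass
class Reaction:
    """One column of the stoichiometric matrix.

    ``stoichiometry`` maps metabolite id -> coefficient (negative = consumed).
    Exchange reactions touch exactly one non-boundary metabolite; the boundary
    side is implicit.
    """

    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = BIG
    role: str = ROLE_INTERNAL

    def validate(self) -> None:
        if self.lb > self.ub:
            raise InvalidModelError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")
        if self.role in (ROLE_EXCHANGE, ROLE_TAXON_EXCHANGE, ROLE_LUMEN_EXCHANGE):
            # taxon-exchange pairs one internal with one lumen metabolite
            limit = 2 if self.role == ROLE_TAXON_EXCHANGE else 1
            if len(self.stoichiometry) != limit:
                raise InvalidModelError(
                    f"exchange reaction {self.id} must touch exactly "
                    f"{limit} metabolite(s), got {len(self.stoichiometry)}"
                )


@dataclass
class TaxonModel:
    """One organism's stoichiometric network with a single biomass reaction."""

    taxon: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str

    def validate(self) -> None:
        biomass = [r for r in self.reactions if r.role == ROLE_BIOMASS]
        if len(biomass) != 1:
            raise InvalidModelError(
                f"taxon {self.taxon}: expected exactly one biomass reaction, got {len(biomass)}"
            )
        if biomass[0].id != self.biomass_id:
            raise InvalidModelError(
                f"taxon {self.taxon}: biomass_id {self.biomass_id!r} does not match "
                f"the biomass reaction {biomass[0].id!r}"
            )
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise InvalidModelError(f"taxon {self.taxon}: duplicate reaction ids")
        met_ids = {m.id for m in self.metabolites}
        for r in self.reactions:
            r.validate()
            unknown = set(r.stoichiometry) - met_ids
            if unknown:
                raise InvalidModelError(
                    f"taxon {self.taxon}: reaction {r.id} references unknown metabolites {sorted(unknown)}"
                )

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.role == ROLE_EXCHANGE]

    def exchange_metabolites(self) -> list[str]:
        """Metabolites this taxon can exchange with its surroundings."""
        mets = []
        for r in self.exchange_reactions:
            (met,) = r.stoichiometry
            mets.append(met)
        return mets

    def copy(self) -> "TaxonModel":
        return copy.deepcopy(self)


@dataclass
class DietSpec:
    """Per-nutrient environment uptake bounds with macro class and energy density.

    ``bounds`` maps an environment exchange id (VMH style, e.g. ``EX_glc(e)``)
    to the maximum uptake flux in mmol/gDW/h.  ``nutrient_class`` assigns each
    entry to carbohydrate/lipid/protein/other; ``energy_density`` is kcal/mmol.
    """

    name: str
    bounds: dict[str, float]
    nutrient_class: dict[str, str]
    energy_density: dict[str, float]

    def __post_init__(self):
        for rid, b in self.bounds.items():
            if b < 0:
                raise InvalidModelError(f"diet {self.name}: negative bound for {rid}")


def exchange_id(met: str) -> str:
    """Environment (lumen) exchange id for a metabolite, VMH style."""
    return f"EX_{met}(e)"


def filter_abundances(raw, cutoff: float = ABUNDANCE_CUTOFF):
    """Drop taxa below the abundance cutoff and renormalize the survivors to sum 1.

    Accepts a pandas Series, a mapping, or an array; returns the same kind.
    Raises :class:`EmptyCommunityError` when nothing survives.
    """
    as_dict = isinstance(raw, dict)
    series = pd.Series(raw, dtype=float)
    if (series < 0).any():
        raise ValueError("abundances must be non-negative")
    total = series.sum()
    if total <= 0:
        raise EmptyCommunityError("abundance vector sums to zero")
    if total > 1 + 1e-9:
        # counts-like input: the cutoff applies to *relative* abundance
        series = series / total
    kept = series[series >= cutoff]
    if kept.empty or kept.sum() == 0:
        raise EmptyCommunityError(
            f"no taxon at or above the abundance cutoff {cutoff}"
        )
    kept = kept / kept.sum()
    if as_dict:
        return kept.to_dict()
    if isinstance(raw, pd.Series):
        return kept
    return kept.to_numpy()


class CommunityModel:
    """Taxa + relative abundances coupled through a shared lumen compartment.

    The assembled model exposes dense arrays (``S``, ``lb``, ``ub``) plus the
    reaction/metabolite bookkeeping needed by the solvers.  Instances are
    immutable in spirit: :func:`apply_diet` returns a modified copy.
    """

    def __init__(self, taxa: list[TaxonModel], abundances):
        if isinstance(abundances, dict):
            abundances = pd.Series(abundances, dtype=float)
        elif not isinstance(abundances, pd.Series):
            abundances = pd.Series(
                np.asarray(abundances, dtype=float), index=[t.taxon for t in taxa]
            )
        labels = [t.taxon for t in taxa]
        if sorted(labels) != sorted(abundances.index):
            missing = set(labels) ^ set(abundances.index)
            raise ValueError(
                f"taxon labels of models and abundances must match 1:1; mismatch: {sorted(missing)}"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate taxon labels in community")
        abundances = abundances.reindex(labels)
        total = abundances.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            abundances = abundances / total
        for model in taxa:
            model.validate()
        self.taxa = [t.copy() for t in taxa]
        self.abundances = abundances
        self.diet: DietSpec | None = None
        self._build()

    # ------------------------------------------------------------------ build
    def _build(self) -> None:
        met_index: dict[str, int] = {}
        rxn_ids: list[str] = []
        rxn_taxon: list[str | None] = []
        rxn_role: list[str] = []
        entries: list[tuple[int, int, float]] = []  # (met_row, rxn_col, coeff)
        lb: list[float] = []
        ub: list[float] = []

        def met_row(mid: str) -> int:
            if mid not in met_index:
                met_index[mid] = len(met_index)
            return met_index[mid]

        lumen_mets: set[str] = set()
        for model in self.taxa:
            for met in model.exchange_metabolites():
                lumen_mets.add(met)
        for met in sorted(lumen_mets):
            met_row(f"{met}_lu")

        biomass_cols: dict[str, int] = {}
        for model, a_i in zip(self.taxa, self.abundances.to_numpy()):
            for r in model.reactions:
                col = len(rxn_ids)
                rxn_ids.append(f"{model.taxon}__{r.id}")
                rxn_taxon.append(model.taxon)
                lb.append(r.lb)
                ub.append(r.ub)
                if r.role == ROLE_EXCHANGE:
                    rxn_role.append(ROLE_TAXON_EXCHANGE)
                    (met,) = r.stoichiometry
                    coeff = r.stoichiometry[met]
                    entries.append((met_row(f"{model.taxon}__{met}"), col, coeff))
                    # positive flux removes met from the private compartment and
                    # delivers a_i * flux into the lumen (abundance coupling)
                    entries.append((met_row(f"{met}_lu"), col, -coeff * a_i))
                else:
                    rxn_role.append(r.role)
                    if r.role == ROLE_BIOMASS:
                        biomass_cols[model.taxon] = col
                    for met, coeff in r.stoichiometry.items():
                        entries.append((met_row(f"{model.taxon}__{met}"), col, coeff))

        env_cols: dict[str, int] = {}
        for met in sorted(lumen_mets):
            col = len(rxn_ids)
            rid = exchange_id(met)
            rxn_ids.append(rid)
            rxn_taxon.append(None)
            rxn_role.append(ROLE_LUMEN_EXCHANGE)
            lb.append(0.0)  # no import unless a diet grants it
            ub.append(BIG)  # secretion to the environment is unbounded
            entries.append((met_row(f"{met}_lu"), col, -1.0))
            env_cols[rid] = col

        n_mets, n_rxns = len(met_index), len(rxn_ids)
        S = np.zeros((n_mets, n_rxns))
        for i, j, coeff in entries:
            S[i, j] += coeff

        self.metabolite_ids = [m for m, _ in sorted(met_index.items(), key=lambda kv: kv[1])]
        self.reaction_ids = rxn_ids
        self.reaction_index = {rid: j for j, rid in enumerate(rxn_ids)}
        self.reaction_taxon = rxn_taxon
        self.reaction_role = rxn_role
        self.S = S
        self.lb = np.array(lb)
        self.ub = np.array(ub)
        self.biomass_cols = biomass_cols
        self.env_cols = env_cols
        self.lumen_metabolites = sorted(lumen_mets)

    # ------------------------------------------------------------- accessors
    @property
    def abundance_vector(self) -> np.ndarray:
        return self.abundances.to_numpy()

    def growth_objective(self) -> np.ndarray:
        """Objective coefficients for community growth mu_c = sum_i a_i mu_i."""
        c = np.zeros(len(self.reaction_ids))
        for taxon, col in self.biomass_cols.items():
            c[col] = float(self.abundances[taxon])
        return c

    def env_exchange_id(self, met: str) -> str:
        return exchange_id(met)

    def with_abundances(self, abundances) -> "CommunityModel":
        """Rebuild the community with new relative abundances (same taxa, same diet)."""
        out = CommunityModel(self.taxa, abundances)
        if self.diet is not None:
            out = apply_diet(out, self.diet)
        return out

    def copy(self) -> "CommunityModel":
        return copy.deepcopy(self)


def assemble_community(models: list[TaxonModel], abundances) -> CommunityModel:
    """Assemble per-taxon models and filtered relative abundances into one community."""
    return CommunityModel(models, abundances)


def apply_diet(community: CommunityModel, diet: DietSpec) -> CommunityModel:
    """Return a copy of the community with environment uptake bounds set from the diet.

    Environment exchanges absent from the diet get uptake bound 0 (their
    secretion stays unbounded).  Diet entries that match no lumen exchange are
    ignored with a logged warning — real diet tables list nutrients that toy
    communities cannot metabolize.
    """
    out = community.copy()
    out.diet = diet
    for rid, col in out.env_cols.items():
        out.lb[col] = 0.0
    unmatched = []
    for rid, bound in diet.bounds.items():
        col = out.env_cols.get(rid)
        if col is None:
            unmatched.append(rid)
            continue
        out.lb[col] = -float(bound)
    if unmatched:
        logger.warning(
            "diet %s: %d entries match no lumen exchange and were ignored: %s",
            diet.name, len(unmatched), ", ".join(sorted(unmatched)),
        )
    return out
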