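"""Serialization: model JSON, SBML-subset import, diet TSV, study CSV, reports.

The native model format is a small JSON schema:

    {"metabolites": [{"id": ..., "compartment": ...}],
     "reactions":   [{"id": ..., "stoichiometry": {met: coeff},
                      "lb": ..., "ub": ..., "is_biomass": bool,
                      "is_exchange": bool}]}

A community file nests taxon models with their relative abundances and an
optional diet block.  SBML import covers the constraint-based subset only —
species, reactions with stoichiometry, flux bounds (fbc attributes or bound
parameters) and a biomass flag; documents using rules, events or constraints
are rejected with a parse error naming the construct.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .errors import InvalidModelError, ParseError
from .model import (
    BIG,
    CommunityModel,
    DietSpec,
    Metabolite,
    Reaction,
    ROLE_BIOMASS,
    ROLE_EXCHANGE,
    ROLE_INTERNAL,
    TaxonModel,
    apply_diet,
    assemble_community,
)

# ------------------------------------------------------------------- models
def taxon_to_dict(model: TaxonModel) -> dict:
    return {
        "taxon": model.taxon,
        "metabolites": [{"id": m.id, "compartment": m.compartment} for m in model.metabolites],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lb": r.lb,
                "ub": r.ub,
                "is_biomass": r.role == ROLE_BIOMASS,
                "is_exchange": r.role == ROLE_EXCHANGE,
            }
            for r in model.reactions
        ],
    }


def taxon_from_dict(data: dict) -> TaxonModel:
    try:
        mets = [Metabolite(m["id"], m.get("compartment", "c")) for m in data["metabolites"]]
        reactions = []
        biomass_id = None
        for r in data["reactions"]:
            if r.get("is_biomass"):
                role = ROLE_BIOMASS
                biomass_id = r["id"]
            elif r.get("is_exchange"):
                role = ROLE_EXCHANGE
            else:
                role = ROLE_INTERNAL
            reactions.append(
                Reaction(
                    r["id"], {k: float(v) for k, v in r["stoichiometry"].items()},
                    lb=float(r.get("lb", 0.0)), ub=float(r.get("ub", BIG)), role=role,
                )
            )
    except KeyError as exc:
        raise ParseError(f"model JSON missing required key {exc}") from exc
    if biomass_id is None:
        raise InvalidModelError(
            f"model {data.get('taxon', '?')!r} declares no biomass reaction"
        )
    model = TaxonModel(data.get("taxon", "taxon"), mets, reactions, biomass_id)
    model.validate()
    return model


def write_taxon(model: TaxonModel, path) -> None:
    Path(path).write_text(json.dumps(taxon_to_dict(model), indent=1, sort_keys=True))


def read_taxon(path) -> TaxonModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON in {path}", context=f"line {exc.lineno}") from exc
    return taxon_from_dict(data)


def write_community(community: CommunityModel, path) -> None:
    data = {
        "taxa": [
            {"abundance": float(community.abundances[m.taxon]), **taxon_to_dict(m)}
            for m in community.taxa
        ],
        "diet": None
        if community.diet is None
        else {
            "name": community.diet.name,
            "bounds": community.diet.bounds,
            "nutrient_class": community.diet.nutrient_class,
            "energy_density": community.diet.energy_density,
        },
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def read_community(path) -> CommunityModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON in {path}", context=f"line {exc.lineno}") from exc
    try:
        models = [taxon_from_dict(t) for t in data["taxa"]]
        abundances = {t["taxon"]: float(t["abundance"]) for t in data["taxa"]}
    except KeyError as exc:
        raise ParseError(f"community JSON missing required key {exc}") from exc
    community = assemble_community(models, abundances)
    if data.get("diet"):
        d = data["diet"]
        community = apply_diet(
            community,
            DietSpec(d["name"], d["bounds"], d["nutrient_class"], d["energy_density"]),
        )
    return community


# --------------------------------------------------------------------- SBML
_SBML_UNSUPPORTED = ("listOfRules", "listOfEvents", "listOfConstraints")


def _strip_sbml_prefix(sid: str, prefix: str) -> str:
    """Remove the conventional SBML id prefix (R_/M_) when present."""
    return sid[len(prefix):] if sid and sid.startswith(prefix) else sid


def read_sbml_taxon(path, taxon: str | None = None) -> TaxonModel:
    """Import the constraint-based subset of an SBML file as a taxon model.

    Maps species, reactions (stoichiometry + bounds) and the biomass flag
    only.  Bounds come from fbc flux-bound parameters when present, else
    from reversibility.  Unsupported SBML constructs raise a parse error
    naming the construct.
    """
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"invalid SBML XML in {path}", context=str(exc)) from exc
    root = doc.getroot()
    ns = {"s": root.nsmap.get(None, ""), "fbc": root.nsmap.get("fbc", "fbc")}
    sbml_model = root.find("s:model", ns)
    if sbml_model is None:
        raise ParseError("no <model> element in SBML document")
    for construct in _SBML_UNSUPPORTED:
        if sbml_model.find(f"s:{construct}", ns) is not None:
            raise ParseError(f"unsupported SBML construct <{construct}>")

    params: dict[str, float] = {}
    for p in sbml_model.findall(".//s:listOfParameters/s:parameter", ns):
        params[p.get("id")] = float(p.get("value", "0"))

    fbc_ns = root.nsmap.get("fbc")
    biomass_ids: set[str] = set()
    if fbc_ns:
        for obj in sbml_model.findall(
            ".//{%s}listOfObjectives//{%s}fluxObjective" % (fbc_ns, fbc_ns)
        ):
            rid = obj.get("{%s}reaction" % fbc_ns)
            if rid:
                biomass_ids.add(_strip_sbml_prefix(rid, "R_"))

    mets = []
    boundary: set[str] = set()
    for sp in sbml_model.findall(".//s:listOfSpecies/s:species", ns):
        sid = _strip_sbml_prefix(sp.get("id"), "M_")
        if sp.get("boundaryCondition", "false") == "true":
            boundary.add(sid)
            continue
        mets.append(Metabolite(sid, sp.get("compartment", "c")))

    reactions = []
    biomass_id = None
    for rx in sbml_model.findall(".//s:listOfReactions/s:reaction", ns):
        rid = _strip_sbml_prefix(rx.get("id"), "R_")
        stoich: dict[str, float] = {}
        for ref in rx.findall("s:listOfReactants/s:speciesRef", ns) + rx.findall(
            "s:listOfReactants/s:speciesReference", ns
        ):
            sid = _strip_sbml_prefix(ref.get("species"), "M_")
            if sid in boundary:
                continue
            stoich[sid] = stoich.get(sid, 0.0) - float(ref.get("stoichiometry", "1"))
        for ref in rx.findall("s:listOfProducts/s:speciesRef", ns) + rx.findall(
            "s:listOfProducts/s:speciesReference", ns
        ):
            sid = _strip_sbml_prefix(ref.get("species"), "M_")
            if sid in boundary:
                continue
            stoich[sid] = stoich.get(sid, 0.0) + float(ref.get("stoichiometry", "1"))
        lb_ref = rx.get("{%s}lowerFluxBound" % fbc_ns) if fbc_ns else None
        ub_ref = rx.get("{%s}upperFluxBound" % fbc_ns) if fbc_ns else None
        reversible = rx.get("reversible", "true") == "true"
        lb = params.get(lb_ref, -BIG if reversible else 0.0) if lb_ref else (-BIG if reversible else 0.0)
        ub = params.get(ub_ref, BIG) if ub_ref else BIG
        is_biomass = rid in biomass_ids or "biomass" in rid.lower()
        role = ROLE_BIOMASS if is_biomass else (
            ROLE_EXCHANGE if len(stoich) == 1 else ROLE_INTERNAL
        )
        if is_biomass:
            biomass_id = rid
        reactions.append(Reaction(rid, stoich, lb=max(lb, -BIG), ub=min(ub, BIG), role=role))
    if biomass_id is None:
        raise InvalidModelError("SBML model declares no biomass objective")
    model = TaxonModel(taxon or sbml_model.get("id", "taxon"), mets, reactions, biomass_id)
    model.validate()
    return model


# ----------------------------------------------------------- tables & trees
def write_diet(diet: DietSpec, path) -> None:
    rows = [
        {
            "reaction_id": rid,
            "max_uptake": bound,
            "class": diet.nutrient_class.get(rid, "other"),
            "energy_density": diet.energy_density.get(rid, 0.0),
        }
        for rid, bound in sorted(diet.bounds.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_diet(path, name: str | None = None) -> DietSpec:
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot read diet TSV {path}", context=str(exc)) from exc
    required = {"reaction_id", "max_uptake", "class", "energy_density"}
    if not required.issubset(frame.columns):
        raise ParseError(
            f"diet TSV {path} missing columns {sorted(required - set(frame.columns))}"
        )
    return DietSpec(
        name or Path(path).stem,
        bounds=dict(zip(frame["reaction_id"], frame["max_uptake"].astype(float))),
        nutrient_class=dict(zip(frame["reaction_id"], frame["class"])),
        energy_density=dict(zip(frame["reaction_id"], frame["energy_density"].astype(float))),
    )


def write_study(study, directory) -> dict[str, Path]:
    """Write abundance/counts/metadata CSVs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": directory / "abundance.csv",
        "counts": directory / "counts.csv",
        "metadata": directory / "metadata.csv",
    }
    study.abundance.rename_axis("sample_id").to_csv(paths["abundance"])
    study.counts.rename_axis("sample_id").to_csv(paths["counts"])
    study.metadata.to_csv(paths["metadata"])
    return paths


def read_study(directory):
    from .synthetic import PairedStudy

    directory = Path(directory)
    abundance = pd.read_csv(directory / "abundance.csv", index_col="sample_id")
    counts = pd.read_csv(directory / "counts.csv", index_col="sample_id")
    metadata = pd.read_csv(directory / "metadata.csv", index_col="sample_id")
    return PairedStudy(abundance=abundance, counts=counts, metadata=metadata)
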