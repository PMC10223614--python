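"""Synthetic inputs: toy taxon models, diets, paired abundance studies, phylogenies.

Everything the pipeline consumes is generated here, so the whole analysis
builds and tests without any download.  The generator emulates the structure
of a gut-microbiome case/control study of age- and gender-matched pairs
(ADHD vs neurotypical Control), with a 12-taxon roster of named gut species
whose producer/consumer roles follow the field's consensus: *Bacteroides* and
*Prevotella* species secreting acetate and propionate, *Coprococcus* and
*Subdoligranulum* species producing butyrate from cross-fed acetate,
*Bifidobacterium adolescentis* as an acetate/formate fermenter, *Ruminococcus
bromii* as the starch degrader, and *Lacticaseibacillus rhamnosus* as the
probiotic.

Toy taxon models are linear uptake→conversion→biomass chains with
growth-coupled secretion: one mol of carbon source yields ``growth_yield``
gDW of biomass and ``secretion_yield[m]`` mol of each product, so every flux
in the model is proportional to the growth rate and the community solution is
fully determined.  The healthy-community preset is calibrated so lumen SCFA
export sits at the canonical healthy acetate:butyrate:propionate ratio of
3:1:1 (a generator calibration constant, fixed here, not fitted at test
time).

Diet specifications realize printed macro-nutrient energy fractions as
exchange-bound tables using Atwater energy factors (4 kcal/g carbohydrate and
protein, 9 kcal/g lipid) converted to kcal/mmol via molar masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidModelError
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
    filter_abundances,
)

#: short metabolite ids -> human-readable names
METABOLITE_NAMES = {
    "glc": "glucose",
    "strch": "starch",
    "ac": "acetate",
    "but": "butyrate",
    "ppa": "propionate",
    "for": "formate",
    "glu_L": "glutamate",
    "trp_L": "tryptophan",
    "tyr_L": "tyrosine",
    "phe_L": "phenylalanine",
    "h2": "H2",
    "ocdca": "oleate",
    "na1": "sodium",
    "cl": "chloride",
    "h2o": "water",
    "othr": "misc-energy",
}

#: lumen exchange fluxes examined throughout the analysis
SCFA_PANEL = ["ac", "but", "ppa", "for"]
PRECURSOR_PANEL = ["glu_L", "trp_L", "tyr_L", "phe_L"]
DEFAULT_PANEL = SCFA_PANEL + PRECURSOR_PANEL


@dataclass(frozen=True)
class TaxonArchetype:
    """Metabolic phenotype template for one taxon.

    ``secretion_yield`` is mol product per mol carbon source; ``growth_yield``
    is gDW biomass per mmol carbon source (so maximal growth is
    ``uptake_capacity * growth_yield`` 1/h).  ``co_substrate_yield`` lists
    additional consumed metabolites (mol per mol carbon source) that must be
    drawn from the lumen — the cross-feeding hook.
    """

    name: str
    carbon_source: str
    secretion_yield: dict[str, float] = field(default_factory=dict)
    co_substrate_yield: dict[str, float] = field(default_factory=dict)
    growth_yield: float = 0.05
    uptake_capacity: float = 10.0

    def __post_init__(self):
        overlap = set(self.secretion_yield) & (
            set(self.co_substrate_yield) | {self.carbon_source}
        )
        if overlap:
            raise InvalidModelError(
                f"{self.name}: secretes and consumes overlap on {sorted(overlap)}"
            )
        if self.growth_yield <= 0 or self.uptake_capacity <= 0:
            raise InvalidModelError(f"{self.name}: yields must be positive")
        if any(y < 0 for y in self.secretion_yield.values()):
            raise InvalidModelError(f"{self.name}: negative secretion yield")
        if any(y <= 0 for y in self.co_substrate_yield.values()):
            raise InvalidModelError(f"{self.name}: co-substrate yields must be positive")

    @property
    def secretes(self) -> frozenset:
        return frozenset(self.secretion_yield)

    @property
    def consumes(self) -> frozenset:
        return frozenset(self.co_substrate_yield) | {self.carbon_source}


@dataclass(frozen=True)
class EffectSpec:
    """Plantable group differences for the paired-study generator.

    ``abundance_shifts`` are log-fold changes applied to the ADHD member of
    each pair; ``elastic_taxa`` are the taxa whose ADHD-side elasticity
    variance is inflated ``variance_inflation``-fold (realized as a strain
    variant of the taxon's secretion profile at community-build time);
    ``noise_sd`` is the standard deviation of independent per-member
    log-abundance noise.
    """

    elastic_taxa: frozenset = frozenset()
    abundance_shifts: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.015
    seed: int = 0
    variance_inflation: float = 3.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not all(math.isfinite(v) for v in self.abundance_shifts.values()):
            raise ValueError("abundance_shifts must be finite")
        if self.variance_inflation < 1:
            raise ValueError("variance_inflation must be >= 1")
        object.__setattr__(self, "elastic_taxa", frozenset(self.elastic_taxa))


# --------------------------------------------------------------------- roster
# Net SCFA secretion sums to acetate 7.2 : butyrate 2.4 : propionate 2.4
# (mol per mol carbon source, equal abundances) = the calibrated 3:1:1.
DEFAULT_ARCHETYPES: tuple[TaxonArchetype, ...] = (
    TaxonArchetype("A_putredinis", "glc", {"ac": 1.3, "ppa": 0.3, "h2": 0.5}),
    TaxonArchetype("B_uniformis", "glc", {"ac": 1.5, "ppa": 0.6}),
    TaxonArchetype("B_vulgatus", "glc", {"ppa": 1.2, "glu_L": 0.2}),
    TaxonArchetype(
        "B_adolescentis", "glc", {"ac": 1.8, "for": 0.8},
        co_substrate_yield={"phe_L": 0.02, "tyr_L": 0.02},
    ),
    TaxonArchetype("C_catus", "glc", {"but": 0.8}, co_substrate_yield={"ac": 0.5}),
    TaxonArchetype("C_comes", "glc", {"but": 0.7, "ac": 0.3}),
    TaxonArchetype("C_aerofaciens", "glc", {"ac": 0.8, "for": 0.5, "h2": 0.3}),
    TaxonArchetype("S_variabile", "glc", {"but": 0.9}, co_substrate_yield={"ac": 0.5}),
    TaxonArchetype("P_copri", "glc", {"ac": 1.0, "for": 0.5, "ppa": 0.3}),
    TaxonArchetype("R_bromii", "strch", {"for": 0.3}, co_substrate_yield={"ac": 0.4}),
    TaxonArchetype(
        "D_longicatena", "glc", {"ac": 1.3, "h2": 0.4},
        co_substrate_yield={"trp_L": 0.05},
    ),
    TaxonArchetype("L_rhamnosus", "glc", {"ac": 0.6}),
)

DEFAULT_ROSTER: dict[str, TaxonArchetype] = {a.name: a for a in DEFAULT_ARCHETYPES}
DEFAULT_TAXA: list[str] = [a.name for a in DEFAULT_ARCHETYPES]

#: taxon designated to carry the planted elasticity effect by default; the
#: butyrate producer cross-feeding on acetate has the strongest deterministic
#: producer/consumer contrast across the SCFA panel, and designating a single
#: taxon keeps planted strain variants from diluting each other through shared
#: product pools
DEFAULT_ELASTIC_TAXA = frozenset({"S_variabile"})

PROBIOTIC = "L_rhamnosus"


# ---------------------------------------------------------------- taxon model
def generate_taxon_model(
    archetype: TaxonArchetype, size: int | None = None, seed: int = 0
) -> TaxonModel:
    """Build a mass-balanced toy model realizing an archetype.

    The model is an uptake → conversion-chain → biomass backbone with one
    secretion exchange per declared product.  ``size`` asks for a total
    reaction count; extra reactions lengthen the internal conversion chain
    (each intermediate appears in exactly two reactions, keeping the network
    mass-balanced).  The biomass reaction is normalized so unit flux equals a
    growth rate of 1/h.  Output is deterministic for a given archetype and
    seed.
    """
    del seed  # construction is deterministic; kept for the generator contract
    if not archetype.carbon_source:
        raise ValueError(f"{archetype.name}: no energy source declared")
    n_min = 1 + len(archetype.co_substrate_yield) + 1 + 1 + len(archetype.secretion_yield)
    if size is None:
        size = max(n_min, 3)
    elif size < 4:
        raise ValueError(f"size must be >= 4 (uptake, conversion, biomass, secretion); got {size}")
    n_steps = max(1, size - n_min + 1)

    mets = [Metabolite(archetype.carbon_source)]
    reactions = [
        Reaction(
            f"EX_{archetype.carbon_source}",
            {archetype.carbon_source: -1.0},
            lb=-archetype.uptake_capacity,
            ub=BIG,
            role=ROLE_EXCHANGE,
        )
    ]
    for met in sorted(archetype.co_substrate_yield):
        mets.append(Metabolite(met))
        reactions.append(
            Reaction(f"EX_{met}", {met: -1.0}, lb=-BIG, ub=BIG, role=ROLE_EXCHANGE)
        )

    products = {m: y for m, y in sorted(archetype.secretion_yield.items()) if y > 0}
    head_stoich = {archetype.carbon_source: -1.0}
    for met, y in archetype.co_substrate_yield.items():
        head_stoich[met] = -y
    tail_stoich = {"X_bm": archetype.growth_yield / 1.0}
    for met, y in products.items():
        tail_stoich[met] = y

    chain_mets = [f"I{k}" for k in range(1, n_steps)]
    if n_steps == 1:
        reactions.append(Reaction("CONV1", {**head_stoich, **tail_stoich}))
    else:
        reactions.append(Reaction("CONV1", {**head_stoich, chain_mets[0]: 1.0}))
        for k in range(1, n_steps - 1):
            reactions.append(Reaction(f"CONV{k + 1}", {chain_mets[k - 1]: -1.0, chain_mets[k]: 1.0}))
        reactions.append(Reaction(f"CONV{n_steps}", {chain_mets[-1]: -1.0, **tail_stoich}))
    mets.extend(Metabolite(m) for m in chain_mets)
    mets.append(Metabolite("X_bm"))
    # biomass normalized: unit flux consumes 1 g of precursor = 1/h growth
    reactions.append(Reaction("biomass", {"X_bm": -1.0}, role=ROLE_BIOMASS))

    for met in sorted(archetype.secretion_yield):
        if not any(m.id == met for m in mets):
            mets.append(Metabolite(met))
        reactions.append(Reaction(f"EX_{met}", {met: -1.0}, lb=0.0, ub=BIG, role=ROLE_EXCHANGE))

    model = TaxonModel(archetype.name, mets, reactions, biomass_id="biomass")
    model.validate()
    return model


def default_models(
    roster: dict[str, TaxonArchetype] | None = None,
) -> dict[str, TaxonModel]:
    roster = roster or DEFAULT_ROSTER
    return {name: generate_taxon_model(arch) for name, arch in roster.items()}


# ---------------------------------------------------------------------- diets
#: kcal per mmol: Atwater factor (kcal/g) x molar mass (g/mmol)
_ENERGY_DENSITY = {
    "glc": 4 * 0.180, "strch": 4 * 0.180, "ocdca": 9 * 0.282,
    "glu_L": 4 * 0.147, "trp_L": 4 * 0.204, "tyr_L": 4 * 0.181,
    "phe_L": 4 * 0.165, "othr": 0.5,
    "na1": 0.0, "cl": 0.0, "h2o": 0.0,
}

_CLASS = {
    "glc": "carbohydrate", "strch": "carbohydrate", "ocdca": "lipid",
    "glu_L": "protein", "trp_L": "protein", "tyr_L": "protein",
    "phe_L": "protein", "othr": "other", "na1": "other", "cl": "other",
    "h2o": "other",
}

#: intra-class energy weights of each nutrient
_CLASS_WEIGHT = {
    "glc": 0.7, "strch": 0.3, "ocdca": 1.0,
    "glu_L": 0.4, "trp_L": 0.2, "tyr_L": 0.2, "phe_L": 0.2, "othr": 1.0,
}

#: printed macro energy fractions per diet style (share of total energy)
DIET_FRACTIONS = {
    # typical US macro split; the study's source tables only print the other two
    "western": {"carbohydrate": 0.50, "lipid": 0.35, "protein": 0.15, "other": 0.0},
    "atkins": {"carbohydrate": 0.017, "lipid": 0.70, "protein": 0.24, "other": 0.043},
    "vegan": {"carbohydrate": 0.6335, "lipid": 0.2099, "protein": 0.1566, "other": 0.0},
}

#: total diet energy on the flux basis (kcal per gDW.h); sized so the western
#: carbohydrate supply just limits the default community (diet responses show)
TOTAL_DIET_ENERGY = 12.0

_MINERAL_BOUNDS = {"na1": 10.0, "cl": 10.0, "h2o": 50.0}


def generate_diet(style: str) -> DietSpec:
    """Build a diet exchange-bound table matching a style's printed energy split."""
    style = style.lower()
    if style not in DIET_FRACTIONS:
        raise ValueError(f"unknown diet style {style!r}; known: {sorted(DIET_FRACTIONS)}")
    fractions = DIET_FRACTIONS[style]
    bounds, klass, density = {}, {}, {}
    for met, cls in _CLASS.items():
        rid = f"EX_{met}(e)"
        if met in _MINERAL_BOUNDS:
            bounds[rid] = _MINERAL_BOUNDS[met]
        else:
            share = fractions.get(cls, 0.0) * _CLASS_WEIGHT.get(met, 0.0)
            if share == 0.0:
                continue
            bounds[rid] = TOTAL_DIET_ENERGY * share / _ENERGY_DENSITY[met]
        klass[rid] = cls
        density[rid] = _ENERGY_DENSITY[met]
    return DietSpec(name=style, bounds=bounds, nutrient_class=klass, energy_density=density)


def diet_energy_fractions(diet: DietSpec) -> dict[str, float]:
    """Percent of total dietary energy per macro class.

    Raises ``ValueError`` when the diet carries no energy at all.
    """
    energy: dict[str, float] = {}
    for rid, bound in diet.bounds.items():
        e = bound * diet.energy_density.get(rid, 0.0)
        if e > 0:
            cls = diet.nutrient_class.get(rid, "other")
            energy[cls] = energy.get(cls, 0.0) + e
    total = sum(energy.values())
    if total <= 0:
        raise ValueError(f"diet {diet.name} provides no energy")
    out = {cls: 0.0 for cls in ("carbohydrate", "lipid", "protein", "other")}
    for cls, e in energy.items():
        out[cls] = 100.0 * e / total
    return out


# ----------------------------------------------------------------- phylogeny
def generate_tree(taxa: list[str], seed: int = 0) -> str:
    """Random binary coalescent-style topology with exponential branch lengths.

    Returns a newick string whose leaves are exactly ``taxa``.
    """
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")
    rng = np.random.default_rng(seed)
    lineages = list(taxa)
    rng.shuffle(lineages)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        li = float(rng.exponential(0.2) + 0.01)
        lj = float(rng.exponential(0.2) + 0.01)
        merged = f"({lineages[i]}:{li:.6f},{lineages[j]}:{lj:.6f})"
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)] + [merged]
    return lineages[0] + ";"


# -------------------------------------------------------------- paired study
@dataclass
class PairedStudy:
    """Sample x taxon abundance table organized into matched ADHD/Control pairs.

    ``abundance`` rows sum to one; ``counts`` are matched multinomial draws at
    ``depth`` reads (needed by the singleton/doubleton-based richness
    estimator); ``metadata`` has columns age, gender, status, pair_id indexed
    by sample id.
    """

    abundance: pd.DataFrame
    counts: pd.DataFrame
    metadata: pd.DataFrame
    effect: EffectSpec | None = None
    depth: int = 10_000

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.columns)

    def pair_ids(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["pair_id"]))

    def pair_members(self, pair_id: str) -> tuple[str, str]:
        """(control_sample, adhd_sample) of one pair."""
        rows = self.metadata[self.metadata["pair_id"] == pair_id]
        control = rows[rows["status"] == "Control"].index[0]
        adhd = rows[rows["status"] == "ADHD"].index[0]
        return control, adhd

    def status_of(self, sample_id: str) -> str:
        return str(self.metadata.loc[sample_id, "status"])


def generate_paired_study(
    n_pairs: int,
    taxa: list[str] | None = None,
    effect: EffectSpec | None = None,
    depth: int = 10_000,
    pair_sd: float = 0.15,
) -> PairedStudy:
    """Generate a matched-pair abundance study with plantable group effects.

    Each pair shares age and gender (household/sibling design); the ADHD
    member receives the configured log-fold abundance shifts on top of the
    shared pair profile, and both members get independent log-normal noise of
    sd ``noise_sd``.  Rows are renormalized to relative abundances; integer
    counts are a multinomial draw at ``depth`` reads.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    taxa = list(taxa) if taxa is not None else list(DEFAULT_TAXA)
    if not taxa:
        raise ValueError("taxa must be non-empty")
    effect = effect or EffectSpec()
    rng = np.random.default_rng(effect.seed)
    base = np.full(len(taxa), -math.log(len(taxa)))
    shift = np.array([effect.abundance_shifts.get(t, 0.0) for t in taxa])

    rows, meta = {}, {}
    genders = ["Female", "Male"]
    for p in range(1, n_pairs + 1):
        pair_profile = base + rng.normal(0.0, pair_sd, size=len(taxa))
        age = int(rng.integers(12, 26))
        gender = genders[int(rng.integers(0, 2))]
        for status, extra in (("Control", 0.0), ("ADHD", shift)):
            noise = rng.normal(0.0, effect.noise_sd, size=len(taxa)) if effect.noise_sd else 0.0
            logabund = pair_profile + extra + noise
            abund = np.exp(logabund)
            abund = abund / abund.sum()
            sid = f"{status.upper()}{p:02d}"
            rows[sid] = abund
            meta[sid] = {"age": age, "gender": gender, "status": status, "pair_id": f"P{p:02d}"}

    abundance = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    counts = pd.DataFrame(
        {sid: rng.multinomial(depth, abundance.loc[sid].to_numpy()) for sid in abundance.index},
        index=taxa,
    ).T
    metadata = pd.DataFrame.from_dict(meta, orient="index")
    metadata.index.name = "sample_id"
    return PairedStudy(abundance=abundance, counts=counts, metadata=metadata,
                       effect=effect, depth=depth)


# ------------------------------------------- planted elasticity variance
def _net_yield_matrix(roster: dict[str, TaxonArchetype], panel: list[str]) -> pd.DataFrame:
    """Net mol of each panel metabolite per mol carbon, per unit growth yield."""
    data = {}
    for name, arch in roster.items():
        row = {}
        for met in panel:
            y = arch.secretion_yield.get(met, 0.0) - arch.co_substrate_yield.get(met, 0.0)
            row[met] = y / arch.growth_yield
        data[name] = row
    return pd.DataFrame.from_dict(data, orient="index")


def _quadratic_shares(r: pd.DataFrame, abundances: pd.Series, taxon: str) -> np.ndarray:
    """Taxon's share of each panel flux under the quadratic growth allocation.

    In the interior trade-off regime growth rates are proportional to
    abundances, so lumen flux of metabolite ``m`` is proportional to
    ``sum_i a_i^2 r_im`` and the taxon's share is ``a_k^2 r_km`` over that sum.
    """
    a2 = abundances.reindex(r.index).fillna(0.0) ** 2
    denom = (r.mul(a2, axis=0)).sum(axis=0)
    num = a2[taxon] * r.loc[taxon]
    shares = np.where(np.abs(denom) > 1e-12, num / denom, 0.0)
    return np.asarray(shares, dtype=float)


def _inflated_archetype(
    arch: TaxonArchetype,
    roster: dict[str, TaxonArchetype],
    abundances: pd.Series,
    inflation: float,
    panel: list[str] | None = None,
) -> TaxonArchetype:
    """Strain variant whose secretion-profile spread inflates elasticity variance.

    Products are alternately scaled by ``exp(+-g)``; ``g`` is chosen by
    bisection on the closed-form quadratic-share variance so that the
    variance of the taxon's panel elasticities grows ``inflation``-fold.
    """
    panel = panel or SCFA_PANEL
    products = [m for m in sorted(arch.secretion_yield) if arch.secretion_yield[m] > 0]
    if not products or inflation == 1.0:
        return arch
    signs = {m: (1.0 if k % 2 == 0 else -1.0) for k, m in enumerate(products)}

    def variance(g: float) -> float:
        yields = {
            m: y * math.exp(signs.get(m, 0.0) * g) if m in signs else y
            for m, y in arch.secretion_yield.items()
        }
        variant = replace(arch, secretion_yield=yields)
        r = _net_yield_matrix({**roster, arch.name: variant}, panel)
        shares = _quadratic_shares(r, abundances, arch.name)
        return float(np.var(2.0 * shares))

    base = variance(0.0)
    target = inflation * base
    lo, hi = 0.0, 4.0
    if variance(hi) < target:
        g = hi
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if variance(mid) < target:
                lo = mid
            else:
                hi = mid
        g = 0.5 * (lo + hi)
    yields = {
        m: y * math.exp(signs.get(m, 0.0) * g) if m in signs else y
        for m, y in arch.secretion_yield.items()
    }
    return replace(arch, secretion_yield=yields)


# --------------------------------------------------------------- communities
def community_for_sample(
    study: PairedStudy,
    sample_id: str,
    roster: dict[str, TaxonArchetype] | None = None,
    diet: DietSpec | None = None,
    cutoff: float = 1e-4,
) -> CommunityModel:
    """Build (and diet-bound) the community model of one study sample.

    ADHD members host strain variants of the effect's ``elastic_taxa`` whose
    secretion spread realizes the planted elasticity-variance inflation.
    """
    roster = roster or DEFAULT_ROSTER
    abundances = filter_abundances(study.abundance.loc[sample_id], cutoff=cutoff)
    models = []
    is_adhd = study.status_of(sample_id) == "ADHD"
    effect = study.effect
    for taxon in abundances.index:
        arch = roster[taxon]
        if (
            is_adhd
            and effect is not None
            and taxon in effect.elastic_taxa
            and effect.variance_inflation > 1.0
        ):
            arch = _inflated_archetype(arch, roster, abundances, effect.variance_inflation)
        models.append(generate_taxon_model(arch))
    community = assemble_community(models, abundances)
    if diet is not None:
        community = apply_diet(community, diet)
    return community


def healthy_community(
    diet_style: str = "western",
    roster: dict[str, TaxonArchetype] | None = None,
) -> CommunityModel:
    """The documented healthy preset: equal-abundance default roster + diet.

    Solving this community with the cooperative trade-off yields lumen SCFA
    exports at the calibrated healthy 3:1:1 acetate:butyrate:propionate ratio.
    """
    roster = roster or DEFAULT_ROSTER
    models = [generate_taxon_model(a) for a in roster.values()]
    n = len(models)
    community = assemble_community(models, np.full(n, 1.0 / n))
    return apply_diet(community, generate_diet(diet_style))
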