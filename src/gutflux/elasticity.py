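"""Elasticity coefficients of exchange fluxes and pair classification by variance.

The elasticity of a flux ``v`` with respect to a parameter ``p`` is the
dimensionless log-derivative d ln v / d ln p.  It is estimated by a one-sided
forward difference on the log scale with step ``h`` (default 0.1, i.e. a
native-scale parameter increase of ``e^0.1 - 1`` ≈ 10.5%):

    eps = [ln |v(p * e^h)| - ln |v(p)|] / h

The perturbed community is re-solved with the cooperative trade-off before
the flux is read off.  Flux direction (import/export) is not folded into the
elasticity — the absolute value is used — but is recorded separately.
Parameters are either a taxon's relative abundance (perturbed before
renormalization: the taxon is bumped, then the vector is rescaled to sum 1)
or a diet uptake bound.

Matched ADHD/Control pairs are classified per taxon by comparing the spread
(variance) of the taxon's elasticities across the flux panel between the two
members: a wider ADHD spread labels the pair "ADHD", a wider Control spread
"Control", comparable spreads "Same", and "NA" marks taxa absent from either
member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fba import FLUX_EPSILON, TradeoffConfig, cooperative_tradeoff
from .model import CommunityModel, exchange_id

#: default forward-difference step on the log scale
DEFAULT_STEP = 0.1

#: relative variance-width threshold separating Same from ADHD/Control
VARIANCE_THRESHOLD = 0.2


def native_step_percent(h: float = DEFAULT_STEP) -> float:
    """Native-scale percent increase corresponding to a log-scale step ``h``."""
    return (math.exp(h) - 1.0) * 100.0


@dataclass
class ElasticityRecord:
    """One (flux, parameter) elasticity estimate with direction metadata."""

    flux_id: str
    parameter_id: str
    elasticity: float | None
    direction: str
    step: float = DEFAULT_STEP
    status: str = "ok"  # ok | undefined | infeasible

    @property
    def defined(self) -> bool:
        return self.status == "ok" and self.elasticity is not None


@dataclass(frozen=True)
class PairLabel:
    taxon: str
    label: str  # ADHD | Control | Same | NA


def _validate_parameter(community: CommunityModel, parameter_id: str) -> None:
    kind, _, name = parameter_id.partition(":")
    if kind == "abundance":
        if name not in community.abundances.index:
            raise ValueError(f"unknown taxon parameter {name!r}")
    elif kind == "diet":
        if name not in community.env_cols:
            raise ValueError(f"unknown diet parameter {name!r}")
    else:
        raise ValueError(
            f"parameter id must be 'abundance:<taxon>' or 'diet:<exchange>', got {parameter_id!r}"
        )


def _perturbed_community(community: CommunityModel, parameter_id: str, h: float) -> CommunityModel:
    kind, _, name = parameter_id.partition(":")
    if kind == "abundance":
        if name not in community.abundances.index:
            raise ValueError(f"unknown taxon parameter {name!r}")
        bumped = community.abundances.copy()
        bumped[name] *= math.exp(h)  # renormalization happens on rebuild
        return community.with_abundances(bumped / bumped.sum())
    if kind == "diet":
        col = community.env_cols.get(name)
        if col is None:
            raise ValueError(f"unknown diet parameter {name!r}")
        out = community.copy()
        out.lb[col] *= math.exp(h)  # uptake bound is -lb
        return out
    raise ValueError(
        f"parameter id must be 'abundance:<taxon>' or 'diet:<exchange>', got {parameter_id!r}"
    )


def abundance_parameter(taxon: str) -> str:
    return f"abundance:{taxon}"


def diet_parameter(met: str) -> str:
    return f"diet:{exchange_id(met)}"


def elasticity(
    community: CommunityModel,
    flux_id: str,
    parameter_id: str,
    h: float = DEFAULT_STEP,
    config: TradeoffConfig | None = None,
    baseline=None,
) -> ElasticityRecord:
    """Forward-difference elasticity of one exchange flux w.r.t. one parameter."""
    if h <= 0:
        raise ValueError("step h must be > 0")
    if baseline is None:
        baseline = cooperative_tradeoff(community, config)
    records = elasticity_profile(
        community, [flux_id], [parameter_id], h=h, config=config, baseline=baseline
    )
    return records[0]


def elasticity_profile(
    community: CommunityModel,
    flux_panel: list[str],
    parameter_panel: list[str],
    h: float = DEFAULT_STEP,
    config: TradeoffConfig | None = None,
    baseline=None,
) -> list[ElasticityRecord]:
    """One elasticity record per (flux, parameter) pair, deterministic ordering.

    The community is re-solved once per parameter; all panel fluxes are read
    from the same perturbed solution.  Fluxes below the flux epsilon at
    baseline yield undefined records (never ±inf); infeasible perturbed
    solves flag every record of that parameter.
    """
    if h <= 0:
        raise ValueError("step h must be > 0")
    for pid in parameter_panel:
        _validate_parameter(community, pid)
    if baseline is None:
        baseline = cooperative_tradeoff(community, config)
    records: list[ElasticityRecord] = []
    for pid in parameter_panel:
        try:
            perturbed = _perturbed_community(community, pid, h)
            solution = cooperative_tradeoff(perturbed, config)
            solve_status = "ok" if solution.optimal else "infeasible"
        except Exception:
            solution, solve_status = None, "infeasible"
        for fid in flux_panel:
            v0 = float(baseline.fluxes.get(fid, 0.0))
            direction = baseline.direction(fid)
            if abs(v0) <= FLUX_EPSILON:
                records.append(ElasticityRecord(fid, pid, None, direction, h, "undefined"))
                continue
            if solve_status != "ok":
                records.append(ElasticityRecord(fid, pid, None, direction, h, "infeasible"))
                continue
            v1 = float(solution.fluxes.get(fid, 0.0))
            if abs(v1) <= FLUX_EPSILON:
                # the flux vanished under the perturbation; the log-difference
                # is unbounded, so the record is flagged rather than invented
                records.append(ElasticityRecord(fid, pid, None, direction, h, "undefined"))
                continue
            eps = (math.log(abs(v1)) - math.log(abs(v0))) / h
            records.append(ElasticityRecord(fid, pid, eps, direction, h, "ok"))
    return records


def profile_to_frame(records: list[ElasticityRecord], sample_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "sample_id": sample_id,
            "flux_id": r.flux_id,
            "parameter_id": r.parameter_id,
            "elasticity": r.elasticity if r.defined else float("nan"),
            "direction": r.direction,
            "status": r.status,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def _taxon_variance(records: list[ElasticityRecord], taxon: str) -> float | None:
    pid = abundance_parameter(taxon)
    values = [r.elasticity for r in records if r.parameter_id == pid and r.defined]
    if len(values) < 2:
        return None
    return float(np.var(values, ddof=1))


def compare_pair_variances(
    profile_adhd: list[ElasticityRecord],
    profile_control: list[ElasticityRecord],
    taxon: str,
    threshold: float = VARIANCE_THRESHOLD,
    adhd_present: bool = True,
    control_present: bool = True,
) -> PairLabel:
    """Label a matched pair by the width of one taxon's elasticity spread.

    The variance of the taxon's defined abundance-elasticities across the
    flux panel is computed per member; ADHD if the ADHD variance exceeds the
    Control variance by more than the relative ``threshold``, Control for the
    reverse, Same otherwise.  NA when the taxon is absent from either member
    or fewer than two elasticities are defined on either side.
    """
    if not (adhd_present and control_present):
        return PairLabel(taxon, "NA")
    var_a = _taxon_variance(profile_adhd, taxon)
    var_c = _taxon_variance(profile_control, taxon)
    if var_a is None or var_c is None:
        return PairLabel(taxon, "NA")
    if var_a > var_c * (1.0 + threshold):
        return PairLabel(taxon, "ADHD")
    if var_c > var_a * (1.0 + threshold):
        return PairLabel(taxon, "Control")
    return PairLabel(taxon, "Same")
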