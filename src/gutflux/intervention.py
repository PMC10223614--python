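"""Probiotic intervention: least-squares dose fitting and flux-shift reporting.

The probiotic dose ``m`` is the added relative abundance of the probiotic
taxon ``k`` that brings a sample composition ``x`` closest (least squares)
to a healthy reference composition ``c`` after renormalization:

    m* = argmin_{m >= 0} || (x + m e_k) / (1 + m) - c ||^2

The renormalized composition moves along the straight segment from ``x``
(m = 0) towards the pure-probiotic vertex ``e_k`` (m -> inf), so the
objective is unimodal in ``m``; it is minimized by golden-section search on
a bounded bracket.  After dosing, the same community-building pipeline is
re-run and per-metabolite exchange-flux shifts (percent change plus
direction-flip flags) are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import FLUX_EPSILON, FluxSolution

#: upper end of the dose search bracket, in relative-abundance addition units
MAX_DOSE = 5.0

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class InterventionResult:
    """Outcome of one probiotic intervention on one sample."""

    probiotic: str
    dose: float
    pre: FluxSolution | None = None
    post: FluxSolution | None = None
    percent_change: dict[str, float] = field(default_factory=dict)
    flipped: dict[str, bool] = field(default_factory=dict)
    undefined: set = field(default_factory=set)


def _dose_objective(x: np.ndarray, c: np.ndarray, k: int):
    e_k = np.zeros_like(x)
    e_k[k] = 1.0

    def f(m: float) -> float:
        z = (x + m * e_k) / (1.0 + m)
        d = z - c
        return float(d @ d)

    return f


def fit_probiotic_dose(
    sample, reference, probiotic: str, taxa: list[str] | None = None,
    max_dose: float = MAX_DOSE, tol: float = 1e-8,
) -> float:
    """Least-squares probiotic dose bringing a sample towards a reference.

    ``sample`` and ``reference`` are relative-abundance vectors on the same
    taxon universe (pandas Series or arrays + ``taxa``); ``probiotic`` names
    the dosed taxon.  Returns the non-negative dose minimizing the squared
    compositional distance after renormalization, found by golden-section
    search on [0, ``max_dose``].
    """
    if isinstance(sample, pd.Series):
        taxa = list(sample.index)
        x = sample.to_numpy(dtype=float)
        reference = pd.Series(reference, index=taxa) if not isinstance(reference, pd.Series) else reference
        c = reference.reindex(taxa).to_numpy(dtype=float)
    else:
        if taxa is None:
            raise ValueError("taxa labels required with array input")
        x = np.asarray(sample, dtype=float)
        c = np.asarray(reference, dtype=float)
    if probiotic not in taxa:
        raise ValueError(f"unknown probiotic taxon {probiotic!r}")
    k = taxa.index(probiotic)
    f = _dose_objective(x / x.sum(), c / c.sum(), k)

    lo, hi = 0.0, float(max_dose)
    m1 = hi - _GOLDEN * (hi - lo)
    m2 = lo + _GOLDEN * (hi - lo)
    f1, f2 = f(m1), f(m2)
    while hi - lo > tol:
        if f1 <= f2:
            hi, m2, f2 = m2, m1, f1
            m1 = hi - _GOLDEN * (hi - lo)
            f1 = f(m1)
        else:
            lo, m1, f1 = m1, m2, f2
            m2 = lo + _GOLDEN * (hi - lo)
            f2 = f(m2)
    m = 0.5 * (lo + hi)
    # boundary minima: prefer the exact bracket end when it is at least as good
    candidates = sorted({0.0, m, float(max_dose)})
    m = min(candidates, key=lambda v: (f(v), v))
    return float(max(0.0, m))


def apply_probiotic(study, taxon: str, dose: float, samples: list[str] | None = None):
    """Return a study copy with the probiotic added to the chosen samples.

    The taxon's relative abundance is incremented by ``dose`` and the row is
    renormalized; untreated rows are untouched.  By default every ADHD sample
    is dosed.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    from .synthetic import PairedStudy  # local import to avoid a cycle

    if taxon not in study.abundance.columns:
        raise ValueError(f"unknown taxon {taxon!r}")
    abundance = study.abundance.copy()
    if samples is None:
        samples = [s for s in study.samples if study.status_of(s) == "ADHD"]
    for sid in samples:
        row = abundance.loc[sid].to_numpy(dtype=float)
        row[abundance.columns.get_loc(taxon)] += dose
        abundance.loc[sid] = row / row.sum()
    counts = np.rint(abundance.to_numpy() * study.depth).astype(int)
    return PairedStudy(
        abundance=abundance,
        counts=pd.DataFrame(counts, index=abundance.index, columns=abundance.columns),
        metadata=study.metadata.copy(),
        effect=study.effect,
        depth=study.depth,
    )


def compare_flux_shift(
    pre: FluxSolution, post: FluxSolution, panel: list[str],
    probiotic: str = "", dose: float = 0.0,
) -> InterventionResult:
    """Per-metabolite percent flux change and direction-flip flags.

    ``panel`` lists exchange reaction ids present in both solutions.  The
    percent change is ``100 (post - pre) / |pre|``; pre-fluxes below the flux
    epsilon make the change undefined (flagged, not infinite).  A flip is
    recorded when the flux crosses zero across the epsilon band.
    """
    if not (pre.optimal and post.optimal):
        raise ValueError("both solutions must be optimal")
    result = InterventionResult(probiotic=probiotic, dose=dose, pre=pre, post=post)
    for rid in panel:
        v0 = float(pre.fluxes.get(rid, 0.0))
        v1 = float(post.fluxes.get(rid, 0.0))
        flipped = (
            abs(v0) > FLUX_EPSILON
            and abs(v1) > FLUX_EPSILON
            and math.copysign(1.0, v0) != math.copysign(1.0, v1)
        )
        result.flipped[rid] = flipped
        if abs(v0) <= FLUX_EPSILON:
            result.undefined.add(rid)
            result.percent_change[rid] = float("nan")
        else:
            result.percent_change[rid] = 100.0 * (v1 - v0) / abs(v0)
    return result
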