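"""End-to-end orchestration: generate, build, grow, analyze, intervene, report.

``run_pipeline`` chains every stage on one configuration: synthesize the
paired study and its inputs, filter abundances at the cutoff, assemble and
diet-bound one community per sample, solve cooperative trade-off growth (with
the minimal-intake polish), profile exchange-flux elasticities and label the
matched pairs, compute the diversity report, and apply the probiotic
intervention to the ADHD samples.  Every artifact lands in the output
directory together with a manifest recording the configuration, the derived
per-stage seeds, the growth ratios and a checksum per file — each number in
the report is traceable to a manifest entry.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .diversity import alpha_indices, bray_curtis, f_test_variance, mann_whitney_u, unifrac
from .elasticity import (
    VARIANCE_THRESHOLD,
    abundance_parameter,
    compare_pair_variances,
    elasticity_profile,
    profile_to_frame,
)
from .errors import GutfluxError
from .fba import TradeoffConfig, cooperative_tradeoff, fba
from .intervention import apply_probiotic, compare_flux_shift, fit_probiotic_dose
from .model import exchange_id
from .synthetic import (
    DEFAULT_ELASTIC_TAXA,
    DEFAULT_PANEL,
    DEFAULT_TAXA,
    EffectSpec,
    PROBIOTIC,
    SCFA_PANEL,
    community_for_sample,
    generate_diet,
    generate_paired_study,
    generate_tree,
)

logger = logging.getLogger(__name__)

#: exchange fluxes below this magnitude are reported as insignificant
SIGNIFICANCE_THRESHOLD = 1.0  # mmol/gDCW/h


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    seed: int = 0
    n_pairs: int = 10
    taxa: list[str] = field(default_factory=lambda: list(DEFAULT_TAXA))
    diet_styles: list[str] = field(default_factory=lambda: ["western", "atkins", "vegan"])
    tau: float = 0.7
    abundance_cutoff: float = 1e-4
    elasticity_step: float = 0.1
    variance_threshold: float = VARIANCE_THRESHOLD
    elastic_taxa: list[str] = field(default_factory=lambda: sorted(DEFAULT_ELASTIC_TAXA))
    elasticity_diets: list[str] | None = None  # default: all diet styles
    probiotic: str = PROBIOTIC
    reference_policy: str = "random-control"  # or "paired-control"
    intervention_diet: str = "western"
    out_dir: str = "gutflux_out"

    def __post_init__(self):
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")
        if self.elasticity_step <= 0:
            raise ValueError("elasticity_step must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2^31 from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def summarize_metabolite_panel(
    solutions: dict, statuses: dict, panel: list[str] | None = None
) -> pd.DataFrame:
    """Cross-diet comparison table of lumen exchange fluxes.

    ``solutions`` maps ``(diet, sample_id)`` to a solved FluxSolution.  Rows
    cover metabolite x diet x status with the mean lumen flux, its direction
    and the significance flag at the 1 mmol/gDCW/h threshold.
    """
    panel = panel or DEFAULT_PANEL
    records = []
    frame = pd.DataFrame(
        [
            {
                "metabolite": met,
                "diet": diet,
                "status": statuses[sid],
                "flux": float(sol.fluxes.get(exchange_id(met), 0.0)),
            }
            for (diet, sid), sol in solutions.items()
            for met in panel
        ]
    )
    for (met, diet, status), grp in frame.groupby(["metabolite", "diet", "status"]):
        flux = float(grp["flux"].mean())
        records.append(
            {
                "metabolite": met,
                "diet": diet,
                "status": status,
                "flux": flux,
                "direction": "export" if flux > 0 else ("import" if flux < 0 else "none"),
                "significant": bool(abs(flux) >= SIGNIFICANCE_THRESHOLD),
            }
        )
    return pd.DataFrame(records)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "checksums": {}}
    manifest_path = out / "manifest.json"

    def persist():
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))

    def checkpoint(path: Path):
        manifest["checksums"][path.name] = _sha256(path)

    stage = "generate"
    try:
        effect = EffectSpec(
            elastic_taxa=frozenset(config.elastic_taxa),
            seed=stage_seed(config.seed, "study"),
        )
        study = generate_paired_study(config.n_pairs, config.taxa, effect)
        for path in gio.write_study(study, out).values():
            checkpoint(path)
        tree = generate_tree(config.taxa, seed=stage_seed(config.seed, "tree"))
        (out / "tree.nwk").write_text(tree + "\n")
        checkpoint(out / "tree.nwk")
        diets = {style: generate_diet(style) for style in config.diet_styles}
        for style, diet in diets.items():
            gio.write_diet(diet, out / f"diet_{style}.tsv")
            checkpoint(out / f"diet_{style}.tsv")
        manifest["stages"][stage] = {
            "n_samples": len(study.samples),
            "seeds": {
                "study": stage_seed(config.seed, "study"),
                "tree": stage_seed(config.seed, "tree"),
            },
        }

        stage = "grow"
        tradeoff = TradeoffConfig(tau=config.tau)
        solutions: dict = {}
        ratios: dict = {}
        flux_tables: dict = {}
        for style, diet in diets.items():
            rows = {}
            for sid in study.samples:
                community = community_for_sample(
                    study, sid, diet=diet, cutoff=config.abundance_cutoff
                )
                mu_star = fba(community).community_growth
                sol = cooperative_tradeoff(community, tradeoff)
                solutions[(style, sid)] = sol
                ratios[f"{style}/{sid}"] = (
                    float(sol.community_growth / mu_star) if mu_star > 0 else float("nan")
                )
                rows[sid] = {
                    met: float(sol.fluxes.get(exchange_id(met), 0.0)) for met in DEFAULT_PANEL
                }
            table = pd.DataFrame.from_dict(rows, orient="index")
            table.index.name = "sample_id"
            path = out / f"fluxes_{style}.tsv"
            table.to_csv(path, sep="\t")
            checkpoint(path)
            flux_tables[style] = table
        manifest["stages"][stage] = {"growth_ratio": ratios}
        panel_summary = summarize_metabolite_panel(
            solutions, {s: study.status_of(s) for s in study.samples}
        )
        panel_summary.to_csv(out / "metabolite_panel.tsv", sep="\t", index=False)
        checkpoint(out / "metabolite_panel.tsv")

        stage = "elasticity"
        flux_panel = [exchange_id(m) for m in SCFA_PANEL]
        params = [abundance_parameter(t) for t in config.elastic_taxa]
        elasticity_frames = []
        label_tables = {}
        for style in config.elasticity_diets or config.diet_styles:
            diet = diets[style]
            profiles = {}
            for sid in study.samples:
                community = community_for_sample(
                    study, sid, diet=diet, cutoff=config.abundance_cutoff
                )
                profiles[sid] = elasticity_profile(
                    community, flux_panel, params,
                    h=config.elasticity_step, config=tradeoff,
                    baseline=solutions.get((style, sid)),
                )
                frame = profile_to_frame(profiles[sid], sample_id=sid)
                frame.insert(0, "diet", style)
                elasticity_frames.append(frame)
            grid = {}
            for pid in study.pair_ids():
                control, adhd = study.pair_members(pid)
                grid[pid] = {
                    taxon: compare_pair_variances(
                        profiles[adhd], profiles[control], taxon,
                        threshold=config.variance_threshold,
                        adhd_present=taxon in study.abundance.columns
                        and study.abundance.loc[adhd, taxon] >= config.abundance_cutoff,
                        control_present=taxon in study.abundance.columns
                        and study.abundance.loc[control, taxon] >= config.abundance_cutoff,
                    ).label
                    for taxon in config.elastic_taxa
                }
            labels = pd.DataFrame.from_dict(grid, orient="columns")
            labels.index.name = "taxon"
            path = out / f"pair_labels_{style}.tsv"
            labels.to_csv(path, sep="\t")
            checkpoint(path)
            label_tables[style] = labels
        pd.concat(elasticity_frames, ignore_index=True).to_csv(
            out / "elasticity.tsv", sep="\t", index=False
        )
        checkpoint(out / "elasticity.tsv")
        manifest["stages"][stage] = {
            "records": int(sum(len(f) for f in elasticity_frames)),
            "step": config.elasticity_step,
        }

        stage = "diversity"
        alpha = pd.DataFrame(
            {sid: alpha_indices(study.counts.loc[sid].to_numpy()) for sid in study.samples}
        ).T
        alpha.index.name = "sample_id"
        alpha.to_csv(out / "alpha_diversity.csv")
        checkpoint(out / "alpha_diversity.csv")
        samples = study.samples
        n = len(samples)
        bc = np.zeros((n, n))
        uf_u = np.zeros((n, n))
        uf_w = np.zeros((n, n))
        counts = study.counts.loc[samples].to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                bc[i, j] = bc[j, i] = bray_curtis(counts[i], counts[j])
                uf_u[i, j] = uf_u[j, i] = unifrac(counts[i], counts[j], study.taxa, tree)
                uf_w[i, j] = uf_w[j, i] = unifrac(
                    counts[i], counts[j], study.taxa, tree, weighted=True
                )
        for name, mat in (("bray_curtis", bc), ("unifrac_unweighted", uf_u), ("unifrac_weighted", uf_w)):
            frame = pd.DataFrame(mat, index=samples, columns=samples)
            frame.index.name = "sample_id"
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t")
            checkpoint(path)
        test_rows = []
        adhd_ids = [s for s in samples if study.status_of(s) == "ADHD"]
        control_ids = [s for s in samples if study.status_of(s) == "Control"]
        for index_name in ("richness", "chao1", "shannon", "simpson_D", "evenness"):
            ga = alpha.loc[adhd_ids, index_name].to_numpy()
            gc = alpha.loc[control_ids, index_name].to_numpy()
            mwu = mann_whitney_u(ga, gc)
            test_rows.append(
                {"comparison": f"{index_name} ADHD-vs-Control", "test": "mann-whitney-u",
                 "statistic": mwu["U"], "p": mwu["p"]}
            )
            try:
                ftest = f_test_variance(ga, gc)
                test_rows.append(
                    {"comparison": f"{index_name} ADHD-vs-Control", "test": "f-variance",
                     "statistic": ftest["F"], "p": ftest["p"]}
                )
            except ValueError:
                pass
        pd.DataFrame(test_rows).to_csv(out / "group_tests.tsv", sep="\t", index=False)
        checkpoint(out / "group_tests.tsv")
        manifest["stages"][stage] = {"n_samples": n}

        stage = "intervention"
        rng = np.random.default_rng(stage_seed(config.seed, "intervention"))
        inter_rows = []
        diet = diets.get(config.intervention_diet) or generate_diet(config.intervention_diet)
        for pid in study.pair_ids():
            control, adhd = study.pair_members(pid)
            if config.reference_policy == "paired-control":
                reference = control
            else:
                reference = control_ids[int(rng.integers(0, len(control_ids)))]
            dose = fit_probiotic_dose(
                study.abundance.loc[adhd], study.abundance.loc[reference], config.probiotic
            )
            dosed = apply_probiotic(study, config.probiotic, dose, samples=[adhd])
            pre = solutions.get((config.intervention_diet, adhd)) or cooperative_tradeoff(
                community_for_sample(study, adhd, diet=diet, cutoff=config.abundance_cutoff),
                tradeoff,
            )
            post = cooperative_tradeoff(
                community_for_sample(dosed, adhd, diet=diet, cutoff=config.abundance_cutoff),
                tradeoff,
            )
            shift = compare_flux_shift(
                pre, post, [exchange_id(m) for m in DEFAULT_PANEL],
                probiotic=config.probiotic, dose=dose,
            )
            for met in DEFAULT_PANEL:
                rid = exchange_id(met)
                inter_rows.append(
                    {
                        "pair_id": pid, "sample_id": adhd, "reference": reference,
                        "dose": dose, "metabolite": met,
                        "pre_flux": float(pre.fluxes.get(rid, 0.0)),
                        "post_flux": float(post.fluxes.get(rid, 0.0)),
                        "percent_change": shift.percent_change[rid],
                        "flipped": shift.flipped[rid],
                    }
                )
        pd.DataFrame(inter_rows).to_csv(out / "intervention.tsv", sep="\t", index=False)
        checkpoint(out / "intervention.tsv")
        manifest["stages"][stage] = {
            "probiotic": config.probiotic,
            "mean_dose": float(np.mean([r["dose"] for r in inter_rows])) if inter_rows else 0.0,
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        persist()
        raise GutfluxError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    persist()
    checkpoint(manifest_path)
    return manifest
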