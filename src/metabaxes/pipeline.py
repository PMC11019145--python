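"""End-to-end pipeline runner with a reproducibility manifest.

Stage order: simulate -> preprocess -> mwas -> integrate (incl. scores)
-> transfer -> outcomes (cox/km/grid) -> pathways.  Every stage writes
plain-TSV outputs; the manifest records the config snapshot, seed,
per-stage timings, and content digests of every output.  Because Python
float repr round-trips through TSV losslessly, a cached stage can be
reloaded from disk and downstream recomputation stays bit-identical to
a clean run.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from metabaxes import enrichment as enr
from metabaxes import integrate as integ
from metabaxes import outcomes as outc
from metabaxes import preprocess as prep
from metabaxes import synthetic as synth
from metabaxes.mwas import domain_overlap, mwas_scan
from metabaxes.tableio import (
    file_digest,
    json_digest,
    read_participant_table,
    write_tsv,
)


class PipelineError(RuntimeError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_participants": 2000,
        "n_metabolites": 300,
        "n_phenotypes": 20,
        "n_axes": 4,
        "pair": False,
        "young_axis_scale": 0.6,
    },
    "preprocess": {"presence_min": 0.90, "cv_max": 0.10},
    "mwas": {"fdr": 0.05, "scope": "per-phenotype"},
    "integrate": {
        "prune_threshold": 0.8,
        "min_prop": 0.10,
        "folds": 10,
        "cv_seed": 0,
        "cv_rule": "1se",
    },
    "outcomes": {"horizon_years": 10.0, "tiers": ["minimal", "full"]},
    "pathways": {"enabled": True, "top_k": 50, "top_n": 3},
}


def fixture_config(seed: int = 0) -> dict:
    """Small configuration that completes end-to-end in seconds."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg["seed"] = seed
    cfg["simulate"].update({"n_participants": 400, "n_metabolites": 80, "pair": True})
    cfg["integrate"].update({"folds": 5})
    return cfg


def synthetic_mapping_tables(
    metabolite_ids: list[str],
    n_genes: int = 300,
    n_pathways: int = 12,
    genes_per_metabolite: int = 8,
    seed: int = 0,
) -> enr.MappingTable:
    """Deterministic synthetic metabolite->gene and gene->pathway tables."""
    rng = np.random.default_rng(seed)
    genes = [f"gene_{g:04d}" for g in range(n_genes)]
    map_rows = []
    for met in metabolite_ids:
        chosen = rng.choice(
            n_genes, size=min(genes_per_metabolite, n_genes), replace=False
        )
        scores = rng.uniform(1.0, 100.0, size=len(chosen))
        for g, s in zip(chosen, scores):
            map_rows.append(
                {
                    "metabolite_id": met,
                    "gene_id": genes[g],
                    "mapping_score": round(float(s), 3),
                }
            )
    path_rows = []
    for p in range(n_pathways):
        size = int(rng.integers(5, 30))
        for g in rng.choice(n_genes, size=size, replace=False):
            path_rows.append(
                {
                    "pathway_id": f"path_{p:03d}",
                    "gene_id": genes[g],
                    "pathway_name": f"synthetic pathway {p}",
                }
            )
    return enr.MappingTable(
        mapping=pd.DataFrame(map_rows), pathways=pd.DataFrame(path_rows)
    )


class RunManifest:
    """Config snapshot, seed, stage timings, and output digests."""

    def __init__(self, config: dict, out_dir: Path):
        self.config = config
        self.out_dir = Path(out_dir)
        self.stages: dict[str, dict] = {}

    def record(
        self,
        stage: str,
        signature: str,
        outputs: list[Path],
        seconds: float,
        cached: bool = False,
    ) -> None:
        self.stages[stage] = {
            "signature": signature,
            "seconds": round(seconds, 3),
            "cached": cached,
            "outputs": {
                str(p.relative_to(self.out_dir)): file_digest(p) for p in outputs
            },
        }

    def to_dict(self) -> dict:
        from metabaxes import __version__

        return {
            "version": __version__,
            "config": self.config,
            "stages": self.stages,
        }

    def save(self) -> Path:
        path = self.out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        return path

    @staticmethod
    def load(out_dir: Path | str) -> dict | None:
        path = Path(out_dir) / "manifest.json"
        if not path.exists():
            return None
        with open(path) as fh:
            return json.load(fh)


def _stage_intact(prev: dict | None, out_dir: Path, stage: str, signature: str) -> bool:
    """True when a previous run's stage outputs are present and unmodified."""
    if prev is None or stage not in prev.get("stages", {}):
        return False
    entry = prev["stages"][stage]
    if entry["signature"] != signature:
        return False
    return all(
        (Path(out_dir) / rel).exists() and file_digest(Path(out_dir) / rel) == digest
        for rel, digest in entry["outputs"].items()
    )


def write_cohort(cohort: synth.SyntheticCohort, out_dir: Path, tag: str) -> list[Path]:
    d = Path(out_dir)
    paths = [
        write_tsv(cohort.metabolites.values, d / f"{tag}_metabolites.tsv"),
        write_tsv(cohort.phenotypes, d / f"{tag}_phenotypes.tsv"),
        write_tsv(cohort.covariates, d / f"{tag}_covariates.tsv"),
        write_tsv(cohort.outcomes, d / f"{tag}_outcomes.tsv", index=False),
        write_tsv(cohort.phenotype_meta, d / f"{tag}_phenotype_meta.tsv"),
        write_tsv(cohort.truth.axes, d / f"{tag}_truth_axes.tsv"),
    ]
    if cohort.metabolites.qc is not None:
        paths.append(write_tsv(cohort.metabolites.qc, d / f"{tag}_qc.tsv"))
    sidecar = d / f"{tag}_truth.json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(cohort.config).items()
                },
                "log_hr_per_sd": list(map(float, cohort.truth.log_hr_per_sd)),
                "phenotype_axis": {
                    str(k): int(v) for k, v in cohort.truth.phenotype_axis.items()
                },
            },
            fh,
            indent=2,
            sort_keys=True,
            default=str,
        )
    paths.append(sidecar)
    return paths


def _preprocess_cohort(
    cohort: synth.SyntheticCohort, pcfg: dict
) -> tuple[pd.DataFrame, pd.DataFrame, prep.QCReport]:
    filtered, report = prep.qc_filter(
        cohort.metabolites,
        presence_min=pcfg.get("presence_min", 0.90),
        cv_max=pcfg.get("cv_max", 0.10),
    )
    imputed = prep.impute_half_min(filtered)
    Z, _ = prep.log_standardize(imputed)
    table = prep.PhenotypeTable(values=cohort.phenotypes, meta=cohort.phenotype_meta)
    harm, _ = prep.harmonize_phenotypes(table, heights=cohort.covariates["height_m"])
    return Z, harm, report


def run_pipeline(
    config: dict | None = None, out_dir: Path | str = "out", cache: bool = False
) -> RunManifest:
    """Run every configured stage, writing tables and a manifest.

    With ``cache=True``, a stage whose signature (config + upstream
    signatures) matches the previous manifest and whose output files are
    intact is reloaded from disk instead of recomputed; only downstream
    stages with missing/changed outputs re-run.
    """
    cfg = json.loads(json.dumps(config if config is not None else DEFAULT_CONFIG))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prev = RunManifest.load(out_dir) if cache else None
    manifest = RunManifest(cfg, out_dir)
    seed = int(cfg.get("seed", 0))

    # ---- simulate -------------------------------------------------------
    scfg = dict(cfg["simulate"])
    pair = bool(scfg.pop("pair", False))
    young_axis_scale = float(scfg.pop("young_axis_scale", 0.6))
    gen_cfg = synth.GeneratorConfig(**{**scfg, "seed": seed})
    sig_sim = json_digest(
        {"stage": "simulate", "cfg": scfg, "seed": seed, "pair": pair,
         "young_axis_scale": young_axis_scale}
    )
    t0 = time.perf_counter()
    # simulation is cheap and in-memory cohorts are needed downstream, so
    # it always recomputes; caching only verifies/refreshes its outputs
    if pair:
        train, target = synth.generate_cohort_pair(
            gen_cfg, young_axis_scale=young_axis_scale
        )
    else:
        train, target = synth.generate_cohort(gen_cfg), None
    cached = _stage_intact(prev, out_dir, "simulate", sig_sim)
    if cached:
        outputs = [
            out_dir / rel for rel in prev["stages"]["simulate"]["outputs"]
        ]
    else:
        outputs = write_cohort(train, out_dir, "train")
        if target is not None:
            outputs += write_cohort(target, out_dir, "target")
    manifest.record("simulate", sig_sim, outputs, time.perf_counter() - t0, cached)

    # ---- preprocess -----------------------------------------------------
    pcfg = cfg.get("preprocess", {})
    sig_pre = json_digest({"stage": "preprocess", "cfg": pcfg, "up": sig_sim})
    t0 = time.perf_counter()
    Z_t = harm_t = None
    if _stage_intact(prev, out_dir, "preprocess", sig_pre):
        Z = read_participant_table(out_dir / "train_metabolites_standardized.tsv")
        harm = read_participant_table(out_dir / "train_phenotypes_harmonized.tsv")
        if target is not None:
            Z_t = read_participant_table(out_dir / "target_metabolites_standardized.tsv")
            harm_t = read_participant_table(out_dir / "target_phenotypes_harmonized.tsv")
        outputs = [out_dir / rel for rel in prev["stages"]["preprocess"]["outputs"]]
        manifest.record("preprocess", sig_pre, outputs, time.perf_counter() - t0, True)
    else:
        Z, harm, report = _preprocess_cohort(train, pcfg)
        outputs = [
            write_tsv(Z, out_dir / "train_metabolites_standardized.tsv"),
            write_tsv(harm, out_dir / "train_phenotypes_harmonized.tsv"),
            write_tsv(report.excluded, out_dir / "qc_exclusions.tsv", index=False),
        ]
        if target is not None:
            Z_t, harm_t, _ = _preprocess_cohort(target, pcfg)
            outputs += [
                write_tsv(Z_t, out_dir / "target_metabolites_standardized.tsv"),
                write_tsv(harm_t, out_dir / "target_phenotypes_harmonized.tsv"),
            ]
        manifest.record("preprocess", sig_pre, outputs, time.perf_counter() - t0)

    domain_map = train.phenotype_meta["domain"].to_dict()

    # ---- mwas -----------------------------------------------------------
    mcfg = cfg.get("mwas", {})
    sig_mwas = json_digest({"stage": "mwas", "cfg": mcfg, "up": sig_pre})
    t0 = time.perf_counter()
    if _stage_intact(prev, out_dir, "mwas", sig_mwas):
        results = pd.read_csv(out_dir / "mwas_results.tsv", sep="\t")
        outputs = [out_dir / rel for rel in prev["stages"]["mwas"]["outputs"]]
        manifest.record("mwas", sig_mwas, outputs, time.perf_counter() - t0, True)
    else:
        results = mwas_scan(
            harm,
            Z,
            train.covariates[["age", "sex", "race"]],
            domain_map=domain_map,
            fdr_level=mcfg.get("fdr", 0.05),
            scope=mcfg.get("scope", "per-phenotype"),
        )
        overlap, totals = domain_overlap(results)
        outputs = [
            write_tsv(results, out_dir / "mwas_results.tsv", index=False),
            write_tsv(overlap, out_dir / "domain_overlap.tsv", index=False),
            write_tsv(totals.to_frame(), out_dir / "domain_totals.tsv"),
        ]
        manifest.record("mwas", sig_mwas, outputs, time.perf_counter() - t0)

    # ---- integrate ------------------------------------------------------
    icfg = cfg.get("integrate", {})
    sig_int = json_digest({"stage": "integrate", "cfg": icfg, "up": sig_pre})
    t0 = time.perf_counter()
    if _stage_intact(prev, out_dir, "integrate", sig_int):
        loadings = read_participant_table(out_dir / "axis_loadings.tsv")
        loadings.index.name = "phenotype_id"
        weights = read_participant_table(out_dir / "metabolite_weights.tsv")
        weights.index.name = "metabolite_id"
        vp = read_participant_table(out_dir / "variance_proportions.tsv")[
            "variance_proportion"
        ]
        axes = integ.AgingAxes(
            loadings=loadings,
            weights=weights,
            variance_proportion=vp,
            center=pd.Series(0.0, index=loadings.index),
            labels={c: c for c in loadings.columns},
        )
        score_df = read_participant_table(out_dir / "train_scores.tsv")
        scores = integ.MetabolicScores(scores=score_df, cohort="train")
        outputs = [out_dir / rel for rel in prev["stages"]["integrate"]["outputs"]]
        manifest.record("integrate", sig_int, outputs, time.perf_counter() - t0, True)
    else:
        axes, scores, coeffs, prune_log = integ.integrate(
            harm,
            Z,
            domain_map=domain_map,
            prune_threshold=icfg.get("prune_threshold", 0.8),
            min_prop=icfg.get("min_prop", 0.10),
            folds=icfg.get("folds", 10),
            cv_seed=icfg.get("cv_seed", seed),
            cv_rule=icfg.get("cv_rule", "min"),
            n_components=icfg.get("n_components"),
        )
        outputs = [
            write_tsv(coeffs.B, out_dir / "coefficient_matrix.tsv"),
            write_tsv(axes.loadings, out_dir / "axis_loadings.tsv"),
            write_tsv(axes.weights, out_dir / "metabolite_weights.tsv"),
            write_tsv(
                axes.variance_proportion.to_frame("variance_proportion"),
                out_dir / "variance_proportions.tsv",
            ),
            write_tsv(scores.scores, out_dir / "train_scores.tsv"),
            write_tsv(
                pd.DataFrame(
                    {
                        "removed": prune_log.removed,
                        "trigger_a": [p[0] for p in prune_log.trigger_pairs],
                        "trigger_b": [p[1] for p in prune_log.trigger_pairs],
                        "mean_abs_corr": prune_log.mean_abs_corr,
                    }
                ),
                out_dir / "prune_log.tsv",
                index=False,
            ),
        ]
        manifest.record("integrate", sig_int, outputs, time.perf_counter() - t0)

    # ---- transfer -------------------------------------------------------
    t_scores = None
    if cfg.get("transfer", pair):
        if target is None:
            raise PipelineError("transfer requested but no second cohort configured")
        sig_tr = json_digest({"stage": "transfer", "up": sig_int})
        t0 = time.perf_counter()
        if _stage_intact(prev, out_dir, "transfer", sig_tr):
            t_scores = integ.MetabolicScores(
                scores=read_participant_table(out_dir / "target_scores.tsv"),
                cohort="target",
            )
            outputs = [out_dir / rel for rel in prev["stages"]["transfer"]["outputs"]]
            manifest.record("transfer", sig_tr, outputs, time.perf_counter() - t0, True)
        else:
            t_scores = outc.transfer_scores(axes, Z_t, cohort="target")
            outputs = [write_tsv(t_scores.scores, out_dir / "target_scores.tsv")]
            manifest.record("transfer", sig_tr, outputs, time.perf_counter() - t0)

    # ---- outcome association -------------------------------------------
    ocfg = cfg.get("outcomes", {})
    sig_out = json_digest({"stage": "outcomes", "cfg": ocfg, "up": sig_int})
    t0 = time.perf_counter()
    if _stage_intact(prev, out_dir, "outcomes", sig_out):
        outputs = [out_dir / rel for rel in prev["stages"]["outcomes"]["outputs"]]
        manifest.record("outcomes", sig_out, outputs, time.perf_counter() - t0, True)
    else:
        horizon = float(ocfg.get("horizon_years", 10.0))
        composite = outc.build_composite(train.outcomes, horizon_years=horizon)
        comp_table = composite.table.set_index("participant_id")
        endpoints: dict[str, pd.DataFrame] = {"composite": comp_table}
        for endpoint in synth.ENDPOINTS:
            sub = train.outcomes[train.outcomes["endpoint"] == endpoint]
            endpoints[endpoint] = sub.set_index("participant_id")[
                ["time_years", "event"]
            ]
        cox_rows = []
        for tier in ocfg.get("tiers", ["minimal"]):
            spec = outc.CoxSpec(adjustment_tier=tier)
            for endpoint, table in endpoints.items():
                for comp in scores.scores.columns:
                    try:
                        res = outc.fit_cox(
                            scores.scores[comp],
                            table,
                            train.covariates,
                            spec,
                            endpoint=endpoint,
                        )
                    except outc.OutcomeError as exc:
                        warnings.warn(f"cox {endpoint}/{comp}/{tier} skipped: {exc}")
                        continue
                    cox_rows.append(
                        {
                            "endpoint": endpoint,
                            "axis": comp,
                            "tier": tier,
                            "hr_per_sd": res.hr_per_sd,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "p": res.p,
                            "n": res.n,
                            "n_events": res.n_events,
                            "protective_hr": res.reciprocal_hr,
                        }
                    )
        km_frames = []
        for comp in scores.scores.columns:
            km = outc.km_by_tertile(scores.scores[comp], comp_table)
            km.insert(0, "axis", comp)
            km_frames.append(km)
        if t_scores is not None:
            grid_scores, grid_phen, grid_cov = t_scores.scores, harm_t, target.covariates
        else:
            grid_scores, grid_phen, grid_cov = scores.scores, harm, train.covariates
        grid = outc.association_grid(
            grid_scores,
            grid_phen,
            grid_cov,
            tiers={"minimal": outc.MINIMAL_TIER},
            fdr_level=cfg.get("mwas", {}).get("fdr", 0.05),
        )
        outputs = [
            write_tsv(pd.DataFrame(cox_rows), out_dir / "cox_results.tsv", index=False),
            write_tsv(
                pd.concat(km_frames, ignore_index=True),
                out_dir / "km_tertiles.tsv",
                index=False,
            ),
            write_tsv(grid, out_dir / "association_grid.tsv", index=False),
            write_tsv(composite.table, out_dir / "composite_endpoint.tsv", index=False),
        ]
        manifest.record("outcomes", sig_out, outputs, time.perf_counter() - t0)

    # ---- pathways -------------------------------------------------------
    pw = cfg.get("pathways", {})
    if pw.get("enabled", False):
        sig_pw = json_digest({"stage": "pathways", "cfg": pw, "up": sig_mwas})
        t0 = time.perf_counter()
        if _stage_intact(prev, out_dir, "pathways", sig_pw):
            outputs = [out_dir / rel for rel in prev["stages"]["pathways"]["outputs"]]
            manifest.record("pathways", sig_pw, outputs, time.perf_counter() - t0, True)
        else:
            if pw.get("mapping_tsv"):
                mapping = enr.MappingTable(
                    mapping=pd.read_csv(pw["mapping_tsv"], sep="\t"),
                    pathways=pd.read_csv(pw["pathway_tsv"], sep="\t"),
                )
            else:
                mapping = synthetic_mapping_tables(list(Z.columns), seed=seed)
            per_phen = enr.enrich_per_phenotype(
                results,
                list(Z.columns),
                mapping,
                top_k=pw.get("top_k", 50),
                fdr_level=cfg.get("mwas", {}).get("fdr", 0.05),
            )
            report = enr.top_pathways(per_phen, n=pw.get("top_n", 3))
            outputs = [write_tsv(report, out_dir / "top_pathways.tsv", index=False)]
            manifest.record("pathways", sig_pw, outputs, time.perf_counter() - t0)

    manifest.save()
    return manifest
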