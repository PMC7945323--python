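"""End-to-end orchestration: simulate -> score -> MR -> scan -> endophenotypes.

One YAML configuration drives the whole analysis; every stage writes its
outputs under the run directory with a config-digest header line, and a
JSON manifest records the stage outputs with row counts so a run is
auditable and exactly reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association_scan import call_peaks, scan
from .containers import CohortGenotypes, ScoreMatrix
from .endophenotype_association import (cluster_predictor_profiles,
                                        fit_lmm_grid)
from .endophenotype_builder import (clean_and_impute, fit_endophenotypes,
                                    score_endophenotypes)
from .errors import ConfigurationError, MactelkitError, SparseTableError
from .genetic_scores import (build_scores, harmonise_instruments,
                             write_instrument_tsv)
from .io import (config_digest, write_covariates_csv, write_dosage_tsv,
                 write_table, write_vcf)
from .mendelian_randomisation import (conditional_selection, egger_test,
                                      fdr_adjust, fit_score_association,
                                      quintile_odds_ratio, results_frame)
from .synthetic_cohort import (SimulationConfig, TraitArchitecture,
                               default_config, default_retina_loadings,
                               instrument_sets, simulate_cohort,
                               simulate_retina)

__all__ = ["RunManifest", "load_config", "run_pipeline", "default_pipeline_config"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Record of one pipeline run: config digest, seed, stage outputs."""

    config_digest: str
    seed: int
    version: str
    started: float
    stages: list = field(default_factory=list)
    finished: float | None = None

    def add_stage(self, name: str, outputs: dict) -> None:
        self.stages.append({"name": name, "outputs": outputs})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    def verify(self, out_dir) -> None:
        """Check every referenced output exists with the recorded rows."""
        out_dir = Path(out_dir)
        for stage in self.stages:
            for fname, n_rows in stage["outputs"].items():
                fp = out_dir / fname
                if not fp.exists():
                    raise MactelkitError(
                        f"manifest output missing: {fname}")
                if n_rows is None:
                    continue
                with open(fp) as fh:
                    rows = sum(1 for line in fh
                               if not line.startswith("#")) - 1
                if rows != n_rows:
                    raise MactelkitError(
                        f"{fname}: manifest records {n_rows} rows, "
                        f"file has {rows}")


def default_pipeline_config() -> dict:
    """The bundled demo configuration (small, fast, full coverage)."""
    with open(Path(__file__).parent / "data" / "demo_config.yaml") as fh:
        return yaml.safe_load(fh)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    return cfg


def _sim_config(cfg: dict, seed: int) -> SimulationConfig:
    sim = dict(cfg.get("cohort", {}))
    traits = sim.pop("traits", None)
    if traits is not None:
        sim["traits"] = [TraitArchitecture(**t) for t in traits]
        sim.setdefault("causal_effects", cfg.get("causal_effects", {}))
        return SimulationConfig(seed=seed, **sim)
    return default_config(seed=seed, **sim)


def _count(df: pd.DataFrame) -> int:
    return len(df)


def run_pipeline(config, out_dir, seed: int | None = None) -> RunManifest:
    """Run every stage on one synthetic cohort; idempotent given seed.

    Stage order: simulate, score, mr (marginal + conditional + Egger +
    quintile contrast), scan (conditional + interaction), endopheno
    (simulate retina, clean, fit, score), endo-assoc (LMM grid,
    adaptive BH, locus clustering).  Any stage failure aborts with the
    stage name; outputs written so far are retained.
    """
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    digest = config_digest({"config": cfg, "seed": seed})
    manifest = RunManifest(config_digest=digest, seed=seed,
                           version=__version__, started=time.time())
    stage = "simulate"
    try:
        # ---- simulate ----------------------------------------------------
        simcfg = _sim_config(cfg, seed)
        cohort, traits = simulate_cohort(simcfg)
        instruments = instrument_sets(simcfg, cohort)
        write_dosage_tsv(cohort, out_dir / "dosages.tsv", digest=digest)
        write_covariates_csv(cohort, out_dir / "covariates.csv",
                             digest=digest)
        write_vcf(cohort, out_dir / "genotypes.vcf")
        write_instrument_tsv(instruments, out_dir / "instruments.tsv")
        tr = traits.reset_index(names="subject_id")
        write_table(tr, out_dir / "traits.csv", digest=digest, sep=",")
        manifest.add_stage(stage, {
            "dosages.tsv": cohort.n_subjects,
            "covariates.csv": cohort.n_subjects,
            "genotypes.vcf": None,
            "instruments.tsv": sum(len(i) for i in instruments.values()),
            "traits.csv": len(tr),
        })

        # ---- score -------------------------------------------------------
        stage = "score"
        scores = build_scores(cohort, instruments, standardize=True)
        sdf = scores.frame()
        write_table(sdf, out_dir / "scores.tsv", digest=digest)
        manifest.add_stage(stage, {"scores.tsv": len(sdf)})

        # ---- mendelian randomisation ------------------------------------
        stage = "mr"
        mr_cfg = cfg.get("mr", {})
        alpha = float(mr_cfg.get("alpha", 0.05))
        marginal = [fit_score_association(scores, cohort, t)
                    for t in scores.trait_names]
        adj = fdr_adjust([r.p_raw for r in marginal])
        for r, a in zip(marginal, adj):
            r.p_fdr = float(a)
        mdf = results_frame(marginal)
        write_table(mdf, out_dir / "mr_marginal.tsv", digest=digest)

        selected, trace = conditional_selection(
            scores, cohort, scores.trait_names, alpha=alpha)
        rows = []
        for rnd, results in enumerate(trace, start=1):
            for r in results:
                d = r.as_dict()
                d["round"] = rnd
                rows.append(d)
        cdf = pd.DataFrame(rows)
        cdf["selected_order"] = cdf["target"].map(
            {t: i + 1 for i, t in enumerate(selected)})
        write_table(cdf, out_dir / "mr_conditional.tsv", digest=digest)

        egger_rows = []
        for name, inst in instruments.items():
            harm = harmonise_instruments(inst, cohort)
            if len(harm) < 3:
                continue
            sub = cohort.subset_snps(
                np.array([cohort.snp_index(s) for s in harm.snp_ids]))
            snp_scan = scan(sub)
            tab = snp_scan.table.set_index("snp_id")
            ok = [s for s in harm.snp_ids if s in tab.index]
            if len(ok) < 3:
                continue
            w = harm.table.set_index("snp_id").loc[ok, "weight"].to_numpy()
            beta_d = tab.loc[ok, "beta"].to_numpy()
            try:
                fit = egger_test(np.abs(w), np.sign(w) * beta_d, trait=name)
            except MactelkitError as exc:
                log.warning("Egger skipped for %s: %s", name, exc)
                continue
            egger_rows.append({
                "trait": name, "intercept": fit.intercept,
                "intercept_se": fit.intercept_se,
                "intercept_p": fit.intercept_p, "slope": fit.slope,
                "slope_se": fit.slope_se, "slope_p": fit.slope_p,
                "n_instruments": fit.n_instruments,
            })
        edf = pd.DataFrame(egger_rows)
        write_table(edf, out_dir / "egger.tsv", digest=digest)

        q_trait = mr_cfg.get("quintile_trait") or \
            (selected[0] if selected else scores.trait_names[0])
        contrast = tuple(mr_cfg.get("quintile_contrast", (0, 4)))
        try:
            q = quintile_odds_ratio(scores.column(q_trait), cohort.status,
                                    contrast=contrast)
            qdf = pd.DataFrame([{"trait": q_trait, **q.as_dict()}])
        except SparseTableError as exc:
            qdf = pd.DataFrame([{"trait": q_trait, "error": str(exc)}])
        write_table(qdf, out_dir / "quintile_or.tsv", digest=digest)
        manifest.add_stage(stage, {
            "mr_marginal.tsv": len(mdf),
            "mr_conditional.tsv": len(cdf),
            "egger.tsv": len(edf),
            "quintile_or.tsv": len(qdf),
        })

        # ---- genome-wide scans ------------------------------------------
        stage = "scan"
        scan_cfg = cfg.get("scan", {})
        condition_on = scan_cfg.get("condition_on", selected)
        condition_on = [t for t in condition_on if t in scores.trait_names]
        cond_scores = {t: scores.column(t) for t in condition_on}
        cond = scan(cohort, conditioning_scores=cond_scores)
        threshold = float(scan_cfg.get("threshold", 5e-8))
        peaks = call_peaks(cond, threshold=threshold,
                           window_bp=scan_cfg.get("window_bp", 1_000_000))
        write_table(cond.table, out_dir / "scan_conditional.tsv",
                    digest=digest)
        pk = pd.DataFrame({"lead_snp": peaks})
        write_table(pk, out_dir / "scan_peaks.tsv", digest=digest)
        outputs = {"scan_conditional.tsv": len(cond.table),
                   "scan_peaks.tsv": len(pk)}
        partner = scan_cfg.get("interaction_with") or \
            (condition_on[0] if condition_on else None)
        inter = None
        if partner is not None:
            inter = scan(cohort, conditioning_scores=cond_scores,
                         interaction_with=partner)
            write_table(inter.table, out_dir / "scan_interaction.tsv",
                        digest=digest)
            outputs["scan_interaction.tsv"] = len(inter.table)
        lam = pd.DataFrame([{
            "model": "conditional", "lambda_gc": cond.lambda_gc,
        }] + ([{"model": "interaction", "lambda_gc": inter.lambda_gc}]
              if inter is not None else []))
        write_table(lam, out_dir / "lambda_gc.tsv", digest=digest)
        outputs["lambda_gc.tsv"] = len(lam)
        manifest.add_stage(stage, outputs)

        # ---- endophenotypes ----------------------------------------------
        stage = "endopheno"
        ret_cfg = cfg.get("retina", {})
        effect_trait = ret_cfg.get("effect_trait", "serine")
        effect_size = float(ret_cfg.get("effect_size", 0.4))
        explicit = [s for s in ret_cfg.get("predictor_snps", [])
                    if s in set(cohort.snp_ids)]
        lead_for_retina = list(dict.fromkeys([*explicit, *peaks]))
        lead_for_retina = lead_for_retina[:int(ret_cfg.get("n_lead_snps", 2))]

        # retinal patients are drawn from the simulated cases
        case_idx = np.flatnonzero(cohort.status == 1)
        n_pat = min(simcfg.n_patients_retina, case_idx.size)
        case_idx = case_idx[:n_pat]
        simcfg_r = dataclasses.replace(simcfg, n_patients_retina=n_pat)
        patients = np.array([f"RP{i:05d}" for i in range(n_pat)])
        pred = {effect_trait: scores.column(effect_trait)[case_idx]}
        for sid in lead_for_retina:
            j = cohort.snp_index(sid)
            d = cohort.dosages[case_idx, j].copy()
            m = np.isnan(d)
            if m.any():
                d[m] = d[~m].mean()
            pred[sid] = d
        predictors = pd.DataFrame(pred, index=patients)

        loadings = default_retina_loadings(simcfg_r)
        effects = {effect_trait: np.zeros(simcfg_r.n_factors)}
        effects[effect_trait][0] = effect_size
        for i, sid in enumerate(lead_for_retina):
            v = np.zeros(simcfg_r.n_factors)
            v[min(i + 1, simcfg_r.n_factors - 1)] = effect_size / 2
            effects[sid] = v
        retina, truth = simulate_retina(simcfg_r, loadings,
                                        genetic_effects=effects,
                                        predictors=predictors)
        write_table(retina, out_dir / "retina_raw.csv", digest=digest,
                    sep=",")
        cleaned, report = clean_and_impute(
            retina, max_missing_fraction=float(
                ret_cfg.get("max_missing_fraction", 0.2)))
        with open(out_dir / "cleaning_report.json", "w") as fh:
            json.dump(dataclasses.asdict(report), fh, indent=2)
        n_factors = int(ret_cfg.get("n_factors_fit", simcfg_r.n_factors))
        model = fit_endophenotypes(cleaned, n_factors=n_factors, seed=seed)
        ldf = model.loadings_frame().reset_index(names="series")
        write_table(ldf, out_dir / "endo_loadings.csv", digest=digest,
                    sep=",")
        escores = score_endophenotypes(model, cleaned)
        write_table(escores, out_dir / "endo_scores.csv", digest=digest,
                    sep=",")
        write_table(model.subfield_tags(), out_dir / "endo_subfields.csv",
                    digest=digest, sep=",")
        manifest.add_stage(stage, {
            "retina_raw.csv": len(retina),
            "cleaning_report.json": None,
            "endo_loadings.csv": len(ldf),
            "endo_scores.csv": len(escores),
            "endo_subfields.csv": n_factors,
        })

        # ---- endophenotype association ----------------------------------
        stage = "endo-assoc"
        ea_cfg = cfg.get("endo_assoc", {})
        n_endo = int(ea_cfg.get("n_endophenotypes_tested", n_factors))
        endos = model.factor_names[:n_endo]
        pred_names = list(predictors.columns)
        results = fit_lmm_grid(escores, predictors, endos, pred_names)
        rdf = pd.DataFrame([r.as_dict() for r in results])
        write_table(rdf, out_dir / "lmm_results.tsv", digest=digest)
        coef = rdf.pivot(index="predictor", columns="endophenotype",
                         values="beta")
        write_table(coef.reset_index(), out_dir / "lmm_coefficients.csv",
                    digest=digest, sep=",")
        tree = cluster_predictor_profiles(coef)
        with open(out_dir / "locus_clusters.nwk", "w") as fh:
            fh.write(tree.newick() + "\n")
        manifest.add_stage(stage, {
            "lmm_results.tsv": len(rdf),
            "lmm_coefficients.csv": len(coef),
            "locus_clusters.nwk": None,
        })
    except Exception as exc:
        raise MactelkitError(
            f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    manifest.verify(out_dir)
    return manifest
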