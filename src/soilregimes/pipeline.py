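"""End-to-end driver: preprocess -> fit -> classify -> folds -> enrich -> NMF
-> regression, with per-stage outputs, timings and a run manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import aggregate_taxon, growth_folds, spikein_normalize, survival_folds
from .config import RunConfig
from .enrichment import call_enriched, critical_z, enrichment_zscores, fit_noise_model, n_nonzero_asvs
from .fitting import fit_replicates
from .growth_modes import build_growth_matrix, nmf_decompose
from .io import file_sha256, read_counts, read_timeseries
from .ph_regression import NativePHLasso, build_presence_matrix
from .regimes import RegimeThresholds, classify_frame

log = logging.getLogger("soilregimes")

__all__ = ["RunManifest", "run_pipeline", "fit_panel", "enrich_panel"]

ALL_STAGES = ("fit", "classify", "abundance", "enrich", "nmf", "regress")


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    input_hashes: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # name -> {rows, seconds}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def fit_panel(pairs, config: RunConfig) -> pd.DataFrame:
    """Fit every (soil, pH) condition; median parameters across replicates."""
    rows = []
    bykey: dict = {}
    for p in pairs:
        bykey.setdefault((p.soil_id, p.perturbed_ph), []).append(p)
    for (soil, ph), reps in sorted(bykey.items()):
        params, results = fit_replicates(
            reps, gamma=config.gamma, k_a=config.k_a, k_c_tilde=config.k_c_tilde,
            n_starts=config.n_starts, seed=config.seed)
        rows.append({
            "soil_id": soil, "perturbed_pH": ph,
            "x0_tilde": params.x0_tilde, "C0_tilde": params.C0_tilde,
            "gamma_C0_tilde": params.gamma * params.C0_tilde,
            "A0": params.A0, "A0c": params.A0c,
            "loss": float(np.median([r.loss for r in results])),
            "rmse_norm": float(np.median([r.rmse_norm for r in results])),
            "converged": all(r.converged for r in results),
            "n_replicates": len(reps),
        })
    return pd.DataFrame(rows)


def enrich_panel(table, regime_by_condition: dict, config: RunConfig):
    """Noise models, z-scores and per-regime enriched ASV calls for a panel."""
    meta = table.meta
    spike = table.counts[list(table.spike_ids)].sum(axis=1)
    comm = table.counts.drop(columns=list(table.spike_ids))

    def arm(soil, ph, trt, nitrate):
        m = ((meta["soil_id"] == soil)
             & np.isclose(meta["perturbed_pH"].astype(float), ph)
             & (meta["treatment"] == trt) & (meta["nitrate"] == nitrate)
             & (meta["timepoint"] == "end"))
        samples = meta.index[m].sort_values()
        return comm.loc[samples], spike.loc[samples].to_numpy()

    z_by_cond, crit_by_cond = {}, {}
    for (soil, ph) in regime_by_condition:
        minus, sp_m = arm(soil, ph, "chl-", "+")
        plus, sp_p = arm(soil, ph, "chl+", "+")
        if len(minus) == 0 or len(plus) == 0 or len(minus) != len(plus):
            continue
        try:
            model = fit_noise_model(plus, high_thresh=config.noise_high_thresh,
                                    coverage=config.noise_coverage,
                                    soil_id=soil, perturbed_ph=ph)
        except ValueError as err:
            log.warning("no noise model for %s pH %.1f (%s); condition skipped",
                        soil, ph, err)
            continue
        z_by_cond[(soil, ph)] = enrichment_zscores(
            minus, plus, sp_m, sp_p, model, pseudo=config.pseudo_counts)
        crit_by_cond[(soil, ph)] = critical_z(config.alpha, n_nonzero_asvs(minus, plus))

    # no-nitrate contrast: unperturbed condition per soil, pooled z medians
    nn_scores = []
    for soil in meta["soil_id"].unique():
        m = (meta["soil_id"] == soil) & (meta["nitrate"] == "-") & (meta["timepoint"] == "end")
        if not m.any():
            continue
        ph = float(meta.loc[m, "perturbed_pH"].iloc[0])
        minus, sp_m = arm(soil, ph, "chl-", "-")
        plus, sp_p = arm(soil, ph, "chl+", "-")
        if len(minus) < 2 or len(minus) != len(plus):
            continue
        try:
            model = fit_noise_model(plus, high_thresh=config.noise_high_thresh,
                                    coverage=config.noise_coverage)
        except ValueError:
            continue
        nn_scores.append(enrichment_zscores(minus, plus, sp_m, sp_p, model,
                                            pseudo=config.pseudo_counts))
    nn_z = pd.concat(nn_scores, axis=1).max(axis=1) if nn_scores else None
    calls = call_enriched(
        z_by_cond, crit_by_cond,
        {c: r for c, r in regime_by_condition.items() if c in z_by_cond},
        nn_z=nn_z, nn_z_crit=critical_z(config.alpha, config.nn_n_asv))
    return calls, z_by_cond, crit_by_cond


def run_pipeline(config: RunConfig, synth_config=None, stages=None) -> RunManifest:
    """Run the analysis end to end; with no input paths configured, the
    synthetic generators supply study-structured data.

    Stage failure raises with the stage name; outputs written so far persist.
    """
    from .synthetic import SynthConfig, synth_count_table, synth_soil_gradient

    stages = tuple(stages or ALL_STAGES)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest = RunManifest(config_hash=config.hash(), software_version=__version__)
    for p in (config.timeseries_path, config.counts_path, config.taxonomy_path,
              config.meta_path):
        if p:
            manifest.input_hashes[str(p)] = file_sha256(p)

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                manifest.stages.setdefault(name, {})
                log.info("stage %s ...", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                if exc_type is not None:
                    log.error("stage %s failed after %.1fs", name, dt)
                    raise RuntimeError(f"stage {name!r} failed") from exc
                manifest.stages.setdefault(name, {})["seconds"] = round(dt, 3)
                return False

        return _Timer()

    synth_config = synth_config or SynthConfig(seed=config.seed)

    pairs = truth = None
    params_df = None
    if "fit" in stages:
        with stage("fit"):
            if config.timeseries_path:
                pairs, _ = read_timeseries(config.timeseries_path)
            else:
                panel = synth_soil_gradient(synth_config)
                pairs, truth = panel.pairs, panel.truth
                truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            params_df = fit_panel(pairs, config)
            params_df.to_csv(out / "fitted_params.tsv", sep="\t", index=False)
            manifest.stages["fit"]["rows"] = len(params_df)

    regime_by_cond = {}
    if "classify" in stages and params_df is not None:
        with stage("classify"):
            thr = RegimeThresholds(config.x_thr, config.c_thr)
            classified = classify_frame(params_df, thr)
            classified.to_csv(out / "regimes.tsv", sep="\t", index=False)
            regime_by_cond = {(r["soil_id"], float(r["perturbed_pH"])): r["regime"]
                              for _, r in classified.iterrows()}
            manifest.stages["classify"]["rows"] = len(classified)

    table = phylum_folds = None
    if "abundance" in stages:
        with stage("abundance"):
            if config.counts_path:
                table = read_counts(config.counts_path, config.taxonomy_path,
                                    config.meta_path, ("spike_Escherichia",
                                                       "spike_Parabacteroides"))
                count_truth = None
            else:
                table, count_truth = synth_count_table(synth_config)
            abund, qc = spikein_normalize(table)
            phylum = aggregate_taxon(abund, "phylum")
            phylum_folds = growth_folds(phylum, pseudo=config.pseudo_abundance)
            surv = survival_folds(phylum, pseudo=config.pseudo_abundance)
            phylum_folds.g.to_csv(out / "growth_folds.tsv", sep="\t")
            if surv.s is not None and surv.s.size:
                surv.s.to_csv(out / "survival_folds.tsv", sep="\t")
            (out / "spike_qc.json").write_text(json.dumps({
                "spike_correlation": qc.spike_correlation,
                "spike_fraction_mean": qc.spike_fraction_mean,
                "spike_fraction_sd": qc.spike_fraction_sd,
                "excluded_samples": qc.excluded_samples}, indent=2))
            manifest.stages["abundance"]["rows"] = int(abund.abs.shape[0])

    calls = None
    if "enrich" in stages and table is not None and regime_by_cond:
        with stage("enrich"):
            calls, z_by_cond, _ = enrich_panel(table, regime_by_cond, config)
            for regime, call in calls.items():
                pd.Series(sorted(call.enriched)).to_csv(
                    out / f"enriched_regime_{regime}.tsv", sep="\t",
                    index=False, header=["asv_id"])
            manifest.stages["enrich"]["rows"] = sum(len(c.enriched) for c in calls.values())

    if "nmf" in stages and phylum_folds is not None and phylum_folds.g.size:
        with stage("nmf"):
            G = build_growth_matrix(phylum_folds.g)
            nmf = nmf_decompose(G, rank=config.nmf_rank, seed=config.seed,
                                n_restarts=config.nmf_restarts)
            nmf.W.to_csv(out / "nmf_W.tsv", sep="\t")
            nmf.H.to_csv(out / "nmf_H.tsv", sep="\t")
            (out / "nmf_summary.json").write_text(json.dumps(
                {"variance_retained": nmf.variance_retained}, indent=2))
            manifest.stages["nmf"]["rows"] = int(G.G.shape[0])

    if "regress" in stages and calls is not None and "III" in calls and calls["III"].enriched:
        with stage("regress"):
            iii_conds = [c for c, r in regime_by_cond.items() if r == "III"]
            meta = table.meta
            m = (meta["timepoint"] == "end") & (meta["treatment"] == "chl-") & (
                meta["nitrate"] == "+")
            keys = set(iii_conds)
            samp = [s for s in meta.index[m]
                    if (meta.loc[s, "soil_id"], float(meta.loc[s, "perturbed_pH"])) in keys]
            presence = build_presence_matrix(table, calls["III"].enriched,
                                             level=config.tax_level,
                                             rel_thresh=config.rel_thresh,
                                             sample_ids=samp)
            res = NativePHLasso(presence, folds=config.lasso_folds,
                                seed=config.seed).fit(
                loso=presence.soil_id.nunique() >= 3, n_perm=0)
            summary = {"r2_in": res.r2_in, "r2_loso": res.r2_loso,
                       "alpha": res.alpha,
                       "n_taxa": int(presence.X.shape[1]),
                       "n_samples": int(presence.X.shape[0])}
            (out / "ph_regression.json").write_text(json.dumps(summary, indent=2))
            manifest.stages["regress"]["rows"] = int(presence.X.shape[0])

    manifest.write(out / "manifest.json")
    return manifest
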