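"""End-to-end driver: simulate -> fit behavior -> preprocess -> encode -> correlate.

Each stage writes its outputs under the run directory and reads only
prior-stage files; the manifest records the effective parameters and seeds
so a run is reproducible from its config alone.  All randomness derives
from the single global seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, correlates, encoding, photometry
from .behavior import ChoiceData, SamplerConfig, fit_posterior, summarize_weights
from .io import RunConfig, read_trace, read_trials, write_manifest, write_trace, write_trials

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    pass


def _missing(stage: str, path: Path):
    return StageError(
        f"stage '{stage}': missing input {path} — did an upstream stage run?")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_info: dict = {}
    spec = cohort.default_cohort_spec(
        n_mice=config.n_mice, n_sessions=config.n_sessions,
        trials_per_session=config.trials_per_session, seed=config.seed)

    if "simulate" in config.stages:
        _stage_simulate(spec, config, out, stage_info)
    if "fit_behavior" in config.stages:
        _stage_fit_behavior(config, out, stage_info)
    if "preprocess" in config.stages:
        _stage_preprocess(config, out, stage_info)
    if "fit_encoding" in config.stages:
        _stage_fit_encoding(config, out, stage_info)
    if "correlate" in config.stages:
        _stage_correlate(config, out, stage_info)

    write_manifest(out / "manifest.json", config, stage_info)
    with open(out / "manifest.json") as fh:
        return json.load(fh)


def _stage_simulate(spec, config, out: Path, info: dict):
    region = config.region
    for m in range(spec.n_mice):
        weights = cohort.make_weight_trajectories(spec, m)
        frames = []
        for d in range(spec.n_sessions):
            tr = cohort.simulate_trials(spec, m, d)
            tr = cohort.simulate_choices(
                tr, weights, spec.alpha_true, spec.pi_true,
                np.random.default_rng(
                    np.random.SeedSequence([spec.seed, 3, m, d])))
            frames.append(tr)
            kern = cohort.make_ground_truth_kernels(spec, m, region)
            trace = cohort.simulate_photometry(
                tr, kern, noise_sd=spec.noise_sd, drift_spec=spec.drift,
                seed=np.random.default_rng(
                    np.random.SeedSequence([spec.seed, 4, m, d])),
                region=region,
                hemisphere=spec.hemisphere_per_region[region],
                baseline=100.0)
            write_trace(trace, out / f"trace_raw_m{m}_s{d + 1}.csv")
        write_trials(pd.concat(frames, ignore_index=True),
                     out / f"trials_m{m}.csv")
        np.savetxt(out / f"true_weights_m{m}.csv", weights, delimiter=",",
                   header="bias,right_stim,left_stim,history", comments="")
    info["simulate"] = {"n_mice": spec.n_mice, "n_sessions": spec.n_sessions,
                        "alpha_true": spec.alpha_true, "pi_true": spec.pi_true}


def _stage_fit_behavior(config, out: Path, info: dict):
    results = {}
    for m in range(config.n_mice):
        path = out / f"trials_m{m}.csv"
        if not path.exists():
            raise _missing("fit_behavior", path)
        trials = read_trials(path)
        sampler = SamplerConfig(chains=config.chains, warmup=config.warmup,
                                draws=config.draws,
                                seed=int(np.random.SeedSequence(
                                    [config.seed, 5, m]).generate_state(1)[0]
                                    % (2**31)))
        draws = fit_posterior(ChoiceData.from_trials(trials), sampler=sampler)
        traj = summarize_weights(draws)
        traj.table.to_csv(out / f"behavior_weights_m{m}.csv", index=False)
        results[m] = {"alpha_mean": traj.alpha_mean, "pi_mean": traj.pi_mean,
                      "divergences": draws.diagnostics["divergences"]}
    (out / "behavior_fit_report.json").write_text(json.dumps(results, indent=2))
    info["fit_behavior"] = {"chains": config.chains, "warmup": config.warmup,
                            "draws": config.draws}


def _stage_preprocess(config, out: Path, info: dict):
    qc = {}
    for m in range(config.n_mice):
        for d in range(1, config.n_sessions + 1):
            path = out / f"trace_raw_m{m}_s{d}.csv"
            if not path.exists():
                raise _missing("preprocess", path)
            raw = read_trace(path, stage="raw")
            dff = photometry.compute_dff(raw)
            rep = photometry.qc_recording(dff)
            z = photometry.zscore_session(dff)
            write_trace(z, out / f"trace_z_m{m}_s{d}.csv")
            qc[f"m{m}_s{d}"] = {"pass": rep.passed,
                                "transients": rep.transient_count,
                                "blocks": rep.blocks}
    (out / "qc_report.json").write_text(json.dumps(qc, indent=2))
    info["preprocess"] = {"n_recordings": len(qc)}


def _stage_fit_encoding(config, out: Path, info: dict):
    basis = encoding.make_basis(config.n_basis)
    spec_k = encoding.KernelSpec()
    summaries = []
    for m in range(config.n_mice):
        trials_path = out / f"trials_m{m}.csv"
        if not trials_path.exists():
            raise _missing("fit_encoding", trials_path)
        trials = read_trials(trials_path)
        for d in range(1, config.n_sessions + 1):
            path = out / f"trace_z_m{m}_s{d}.csv"
            if not path.exists():
                raise _missing("fit_encoding", path)
            z = read_trace(path, stage="z")
            sess = trials[trials["session_index"] == d]
            X = encoding.build_design_matrix(sess, basis, spec_k,
                                             n_samples=z.values.size)
            fit = encoding.fit_ridge_evidence(X, z.values)
            kset = encoding.reconstruct_kernels(fit, basis, spec_k)
            r2 = encoding.model_r2(fit, X, z.values, sess)
            for side in ("left", "right"):
                cd = encoding.contrast_dependence(
                    kset, side, metric=config.contrast_metric)
                summaries.append({"mouse": m, "session": d, "side": side,
                                  "contrast_dependence": cd,
                                  "gamma": fit.gamma, "sigma_f2": fit.sigma_f2,
                                  "r2": r2})
    pd.DataFrame(summaries).to_csv(out / "encoding_summaries.csv", index=False)
    info["fit_encoding"] = {"n_basis": config.n_basis,
                            "n_kernels": spec_k.n_kernels}


def _stage_correlate(config, out: Path, info: dict):
    enc_path = out / "encoding_summaries.csv"
    if not enc_path.exists():
        raise _missing("correlate", enc_path)
    enc = pd.read_csv(enc_path)
    rows = []
    per_mouse_r = []
    for m in range(config.n_mice):
        bpath = out / f"behavior_weights_m{m}.csv"
        if not bpath.exists():
            raise _missing("correlate", bpath)
        beh = pd.read_csv(bpath)
        hemi = "left"  # region hemisphere from the cohort default
        contra_side = "right" if hemi == "left" else "left"
        neural = (enc[(enc["mouse"] == m) & (enc["side"] == contra_side)]
                  .set_index("session")["contrast_dependence"])
        weight_name = "right_stim" if contra_side == "right" else "left_stim"
        behavioral = (beh[beh["weight"] == weight_name]
                      .set_index("session")["mean"])
        r = correlates.trajectory_correlation(neural, behavioral)
        rows.append({"mouse": m, "r": r})
        if r is not None:
            per_mouse_r.append(r)
    pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
    report = {"per_mouse_r": per_mouse_r}
    if len(per_mouse_r) >= 2 and np.ptp(per_mouse_r) > 0:
        t, p = correlates.group_ttest(per_mouse_r)
        report |= {"t": t, "p": p}
    (out / "group_test.json").write_text(json.dumps(report, indent=2))
    info["correlate"] = {"n_mice_included": len(per_mouse_r)}
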