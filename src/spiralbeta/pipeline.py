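"""Staged pipeline driver: simulate -> preprocess -> kinematics -> tfr ->
bursts -> periburst -> stats, with per-stage content hashing so a config
change in one stage recomputes only that stage and everything downstream.

All randomness descends from the single top-level ``seed``; every stage
records its parameters in the run log.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from spiralbeta import bursts as bursts_mod
from spiralbeta import io as io_mod
from spiralbeta import kinematics as kin_mod
from spiralbeta import lfp as lfp_mod
from spiralbeta import periburst as pb_mod
from spiralbeta import spectral as spec_mod
from spiralbeta import stats as stats_mod
from spiralbeta.synthetic import SimulationConfig, simulate_cohort

STAGES = ["simulate", "preprocess", "kinematics", "tfr", "bursts", "periburst", "stats"]

DEFAULT_CONFIG = {
    "seed": 0,
    "dataset_root": "dataset",
    "out_root": "results",
    "simulate": {},
    "preprocess": {"artifact_threshold_uv": 10.0},
    "kinematics": {"velocity_smooth_sigma_s": 0.025},
    "tfr": {},
    "bursts": {"percentile": 75.0, "min_duration_s": 0.1},
    "periburst": {"window_s": 0.25, "grid_step_s": 0.05},
    "stats": {"n_perm": 500, "alpha_cluster": 0.05,
              "drop_inaccurate": False, "drop_tremor": False},
}


def merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _hash(obj, prev: str = "") -> str:
    return hashlib.sha256((prev + json.dumps(obj, sort_keys=True)).encode()).hexdigest()[:16]


def _stage_fresh(out_root: Path, stage: str, h: str) -> bool:
    f = out_root / f"{stage}.hash"
    return f.exists() and f.read_text() == h


def _mark_done(out_root: Path, stage: str, h: str) -> None:
    (out_root / f"{stage}.hash").write_text(h)


class Pipeline:
    def __init__(self, config: dict | None = None, base_dir: Path = Path(".")):
        self.config = merge_config(config)
        self.base = Path(base_dir)
        self.dataset_root = self.base / self.config["dataset_root"]
        self.out = self.base / self.config["out_root"]
        self.out.mkdir(parents=True, exist_ok=True)
        self.log: list[dict] = []

    # -- stage hash chain -------------------------------------------------
    def stage_hashes(self) -> dict:
        hashes = {}
        prev = _hash({"seed": self.config["seed"]})
        for stage in STAGES:
            prev = _hash(self.config.get(stage, {}), prev)
            hashes[stage] = prev
        return hashes

    def run(self, stages=None) -> Path:
        stages = stages or STAGES
        hashes = self.stage_hashes()
        for stage in STAGES:
            if stage not in stages:
                continue
            h = hashes[stage]
            if _stage_fresh(self.out, stage, h):
                self.log.append({"stage": stage, "status": "cached"})
                continue
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as err:
                self._write_log()
                raise RuntimeError(f"pipeline stage {stage!r} failed") from err
            _mark_done(self.out, stage, h)
            self.log.append({"stage": stage, "status": "computed",
                             "params": self.config.get(stage, {})})
        self._write_log()
        return self.out

    def _write_log(self) -> None:
        (self.out / "run_log.json").write_text(
            json.dumps({"seed": self.config["seed"], "events": self.log}, indent=2)
        )

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> None:
        sim_cfg = SimulationConfig(**{**self.config["simulate"], "seed": self.config["seed"]})
        cohort = simulate_cohort(sim_cfg)
        io_mod.write_dataset(cohort, self.dataset_root)

    def stage_preprocess(self) -> None:
        manifest = io_mod.read_manifest(self.dataset_root)
        out = self.out / "preprocess"
        out.mkdir(exist_ok=True)
        thr = self.config["preprocess"]["artifact_threshold_uv"]
        qc = []
        for e in manifest.entries:
            epoch = io_mod.read_lfp(manifest.root / e.lfp_file)
            clean = lfp_mod.preprocess_lfp(epoch)
            frac = 0.0
            if clean.stim == "on":
                clean, frac = lfp_mod.suppress_stim_artifact(clean, thr)
            io_mod.write_lfp(clean, out / f"{e.trial_id}.f32")
            qc.append({"trial_id": e.trial_id, "fraction_removed": frac,
                       "unusable": clean.unusable})
        pd.DataFrame(qc).to_csv(out / "qc.tsv", sep="\t", index=False)

    def stage_kinematics(self) -> None:
        manifest = io_mod.read_manifest(self.dataset_root)
        out = self.out / "kinematics"
        (out / "profiles").mkdir(parents=True, exist_ok=True)
        sigma = self.config["kinematics"]["velocity_smooth_sigma_s"]
        rows = []
        for e in manifest.entries:
            kin, _ = io_mod.load_trial(manifest, e)
            kin = kin_mod.preprocess_position(kin)
            profile = kin_mod.tangential_velocity(kin, smooth_sigma_s=sigma)
            summary = kin_mod.trial_summary(profile)
            row = {"trial_id": e.trial_id, "subject": e.subject,
                   "drawing": e.drawing, "stim": e.stim,
                   "tremor_subject": e.tremor_subject, **summary}
            try:
                theta, radius = kin_mod.radius_angle_transform(kin)
                fit = kin_mod.fit_spiral(theta, radius)
                row.update(slope=fit.slope, rmse=fit.rmse)
                residuals, mask = fit.residuals, fit.fitted_mask
            except ValueError as err:
                row.update(slope=np.nan, rmse=np.nan, fit_error=str(err))
                residuals = np.full(kin.t.size, np.nan)
                mask = np.zeros(kin.t.size, bool)
            row["inaccurate"] = kin_mod.detect_self_intersection(kin)
            rows.append(row)
            # rows: t, v, a, residuals, fitted_mask (np.save is byte-deterministic)
            np.save(out / "profiles" / f"{e.trial_id}.npy",
                    np.vstack([profile.t, profile.v, profile.a,
                               residuals, mask.astype(float)]))
        pd.DataFrame(rows).to_csv(out / "trials.tsv", sep="\t", index=False)

    def stage_tfr(self) -> None:
        manifest = io_mod.read_manifest(self.dataset_root)
        pre = self.out / "preprocess"
        out = self.out / "tfr"
        out.mkdir(exist_ok=True)
        warped_by_subj_cond: dict = {}
        bp_rows = []
        for e in manifest.entries:
            epoch = io_mod.read_lfp(pre / f"{e.trial_id}.f32")
            tfr = spec_mod.morlet_tfr(epoch)
            draw_end = epoch.intervals["draw"][1]
            warped = spec_mod.timewarp_tfr(tfr, epoch.intervals["rest"], (0.0, draw_end))
            key = (e.subject, e.drawing, e.stim)
            warped_by_subj_cond.setdefault(key, []).append(warped.power)
            for interval in ("rest", "draw"):
                for band_name, band in (("beta", spec_mod.BETA_BAND),
                                        ("gamma", spec_mod.GAMMA_BAND)):
                    bp_rows.append({
                        "trial_id": e.trial_id, "subject": e.subject,
                        "drawing": e.drawing, "stim": e.stim,
                        "interval": interval, "band": band_name,
                        "power": spec_mod.band_power(epoch, interval, band),
                    })
        pd.DataFrame(bp_rows).to_csv(out / "bandpower.tsv", sep="\t", index=False)

        freqs = spec_mod.TFR_FREQS_HZ
        peak_rows = []
        subj_avgs: dict = {}
        for (subject, drawing, stim), maps in sorted(warped_by_subj_cond.items()):
            avg = np.nanmean(np.stack(maps), axis=0)
            np.save(out / f"warped_{subject}_{drawing}_{stim}.npy", avg)
            subj_avgs.setdefault(subject, []).append(avg)
        for subject, maps in sorted(subj_avgs.items()):
            grand = np.nanmean(np.stack(maps), axis=0)
            tmap = spec_mod.TfrMap(
                freqs=freqs, times=np.arange(grand.shape[1], dtype=float),
                power=grand, warped=True,
                segments={"rest": slice(0, 50), "draw": slice(50, 150)},
            )
            peak_rows.append({"subject": subject,
                              "f_peak": bursts_mod.find_beta_peak(tmap)})
        pd.DataFrame(peak_rows).to_csv(out / "beta_peaks.tsv", sep="\t", index=False)

    def stage_bursts(self) -> None:
        manifest = io_mod.read_manifest(self.dataset_root)
        pre = self.out / "preprocess"
        out = self.out / "bursts"
        out.mkdir(exist_ok=True)
        peaks = pd.read_csv(self.out / "tfr" / "beta_peaks.tsv", sep="\t").set_index("subject")
        pct = self.config["bursts"]["percentile"]
        min_dur = self.config["bursts"]["min_duration_s"]

        envs: dict = {}
        for e in manifest.entries:
            epoch = io_mod.read_lfp(pre / f"{e.trial_id}.f32")
            f_peak = float(peaks.loc[e.subject, "f_peak"])
            env = bursts_mod.beta_envelope(epoch, f_peak)
            envs[e.trial_id] = (env, epoch)

        thresholds = {}
        for e in manifest.entries:
            key = (e.subject, e.drawing, e.stim)
            env, epoch = envs[e.trial_id]
            sl = epoch.interval_slice("rest")
            thresholds.setdefault(key, []).append(env.env[sl])
        thresholds = {k: bursts_mod.rest_threshold(v, pct) for k, v in thresholds.items()}

        event_rows, metric_rows = [], []
        for e in manifest.entries:
            env, epoch = envs[e.trial_id]
            thr = thresholds[(e.subject, e.drawing, e.stim)]
            detected = bursts_mod.detect_bursts(env, thr, min_dur)
            labelled = bursts_mod.assign_intervals(detected, epoch.intervals)
            for b in labelled:
                event_rows.append({
                    "trial_id": e.trial_id, "subject": e.subject,
                    "drawing": e.drawing, "stim": e.stim, "interval": b.interval,
                    "onset_s": b.onset, "offset_s": b.offset,
                    "duration_s": b.duration, "peak_uv": b.peak_amplitude,
                })
            for name, (lo, hi) in epoch.intervals.items():
                sel = [b for b in labelled if b.interval == name]
                m = bursts_mod.burst_metrics(sel, hi - lo)
                metric_rows.append({
                    "trial_id": e.trial_id, "subject": e.subject,
                    "drawing": e.drawing, "stim": e.stim, "interval": name,
                    **{k: v for k, v in asdict(m).items()},
                })
        pd.DataFrame(event_rows).to_csv(out / "events.tsv", sep="\t", index=False)
        pd.DataFrame(metric_rows).to_csv(out / "metrics.tsv", sep="\t", index=False)

    def stage_periburst(self) -> None:
        manifest = io_mod.read_manifest(self.dataset_root)
        out = self.out / "periburst"
        out.mkdir(exist_ok=True)
        events = pd.read_csv(self.out / "bursts" / "events.tsv", sep="\t")
        window = self.config["periburst"]["window_s"]
        step = self.config["periburst"]["grid_step_s"]
        rows = []
        rng = np.random.default_rng(self.config["seed"])
        for e in manifest.entries:
            arr = np.load(self.out / "kinematics" / "profiles" / f"{e.trial_id}.npy")
            profile = kin_mod.VelocityProfile(t=arr[0], v=arr[1], a=arr[2])
            draw_span = (0.0, e.draw_duration)
            ev = events[(events["trial_id"] == e.trial_id) & (events["interval"] == "draw")]
            onsets = ev["onset_s"].to_numpy()
            covs = [{"duration": d, "peak_amplitude": p}
                    for d, p in zip(ev["duration_s"], ev["peak_uv"])]
            mode_onsets = {
                "real": (onsets, covs),
                "linear": (pb_mod.control_onsets(draw_span, "linear", step=step,
                                                 window=window), None),
                "shuffled": (pb_mod.control_onsets(draw_span, "shuffled",
                                                   real_onsets=onsets, window=window,
                                                   seed=rng), None),
            }
            for mode, (ons, cv) in mode_onsets.items():
                samples, n_excl = pb_mod.peri_burst_segments(
                    profile, ons, draw_span=draw_span, window=window,
                    covariates=cv, mode=mode)
                for s in samples:
                    rows.append({**asdict(s), "trial_id": e.trial_id,
                                 "subject": e.subject, "drawing": e.drawing,
                                 "stim": e.stim, "mode": mode})
        pd.DataFrame(rows).to_csv(out / "samples.tsv", sep="\t", index=False)

    def stage_stats(self) -> None:
        out = self.out / "stats"
        out.mkdir(exist_ok=True)
        cfg = self.config["stats"]
        trials = pd.read_csv(self.out / "kinematics" / "trials.tsv", sep="\t")
        trials, excl_report = stats_mod.exclusion_filters(
            trials, cfg["drop_inaccurate"], cfg["drop_tremor"])
        results = {"exclusions": excl_report, "models": {}, "clusters": {}}

        n_subjects = trials["subject"].nunique()
        def _try_model(name, frame, spec):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = stats_mod.fit_mixed_model(frame, spec)
            except ValueError as err:
                results["models"][name] = {"error": str(err)}
                return
            results["models"][name] = {
                "coefficients": json.loads(res.coefficients.to_json(orient="index")),
                "n_used": res.n_used, "converged": res.converged,
            }

        if n_subjects >= 5:
            for dep in ("log_mean_velocity", "rmse", "slope"):
                _try_model(dep, trials,
                           stats_mod.ModelSpec(dependent=dep, fixed=["drawing * stim"]))
            samples = pd.read_csv(self.out / "periburst" / "samples.tsv", sep="\t")
            long = samples.melt(
                id_vars=["trial_id", "subject", "drawing", "stim", "mode"],
                value_vars=["a_pre", "a_post"], var_name="interval", value_name="accel")
            for mode in ("real", "linear", "shuffled"):
                sub = long[long["mode"] == mode]
                if sub.empty:
                    continue
                _try_model(f"accel_{mode}", sub,
                           stats_mod.ModelSpec(dependent="accel",
                                               fixed=["interval * stim * drawing"]))
            results["clusters"] = self._cluster_stats(cfg)
        else:
            results["note"] = "fewer than 5 subjects: inferential models skipped"
        (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))

    def _cluster_stats(self, cfg: dict) -> dict:
        tfr_dir = self.out / "tfr"
        manifest = io_mod.read_manifest(self.dataset_root)
        freqs = spec_mod.TFR_FREQS_HZ
        beta_rows = (freqs >= spec_mod.BETA_BAND[0]) & (freqs <= spec_mod.BETA_BAND[1])
        out = {}
        for drawing in ("free", "template"):
            for stim in ("off", "on"):
                draw_early, draw_late, rest = [], [], []
                for subject in sorted({e.subject for e in manifest.entries}):
                    f = tfr_dir / f"warped_{subject}_{drawing}_{stim}.npy"
                    if not f.exists():
                        continue
                    power = np.load(f)[beta_rows]
                    rest.append(power[:, 0:50])
                    draw_early.append(power[:, 50:100])
                    draw_late.append(power[:, 100:150])
                if len(rest) < 5:
                    continue
                for name, seg in (("early", draw_early), ("late", draw_late)):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = spec_mod.cluster_permutation_test(
                            np.stack(seg), np.stack(rest),
                            alpha_cluster=cfg["alpha_cluster"],
                            n_perm=cfg["n_perm"], seed=self.config["seed"])
                    out[f"{drawing}_{stim}_{name}"] = {
                        "n_clusters": len(res.masses),
                        "masses": res.masses.tolist(),
                        "p_values": res.p_values.tolist(),
                    }
        return out


def run_pipeline(config: dict | None = None, base_dir: Path = Path("."), stages=None) -> Path:
    """Execute the staged pipeline; returns the results directory."""
    return Pipeline(config, base_dir).run(stages)
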