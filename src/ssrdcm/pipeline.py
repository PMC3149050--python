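"""End-to-end orchestration: simulate → features → invert → compare → dose.

Two layers: in-memory helpers (:func:`invert_study`, :func:`analyse_study`)
used directly from Python, and a file-based :func:`run_pipeline` that
persists every stage's outputs under an output directory with a run
manifest (stage status, timing, config hash) and skips completed stages on
re-runs unless forced.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as _io
from .dcm import fit_recording
from .dose_stats import (build_effect_table, dose_response_curves,
                         group_coefficient_test, one_way_anova,
                         overall_effect_test)
from .errors import SSRDCMError
from .inversion import VLSettings
from .model_comparison import average_hemispheres, select_model
from .spectral_features import series_to_csd
from .synthetic import StudyConfig, StudyData, generate_study
from . import __version__

__all__ = ["invert_study", "analyse_study", "run_pipeline", "RunManifest",
           "StudyAnalysis"]

DEFAULT_MODELS = ("FB", "BF", "LL")


def _records_to_sites(records, key_mode="csd"):
    """Group per-recording records into per-site condition dictionaries."""
    sites = {}
    for rec in records:
        key = (rec["animal"], rec["hemisphere"], rec["environment"])
        sites.setdefault(key, {})[rec["dose"]] = rec[key_mode]
    return sites


def invert_study(study: StudyData, models=DEFAULT_MODELS,
                 settings: VLSettings | None = None,
                 var_order: int = 8, progress=None):
    """Fit every recording site under every architecture.

    For a time-series study the spectral features are computed first
    (VAR(var_order) → CSD).  Returns ``(evidence, posteriors)``: a tidy
    DataFrame of per-recording log-evidences and a list of posterior
    records (dicts with animal/hemisphere/environment/model/posterior).
    """
    settings = settings or VLSettings()
    if study.mode == "timeseries":
        csd_records = []
        for rec in study.records:
            sim = rec["series"]
            csd = series_to_csd(sim.data, fs_in=sim.fs,
                                epoch_seconds=sim.t[-1] + sim.dt,
                                order=var_order, channels=sim.channels)
            csd_records.append({**rec, "csd": csd})
    else:
        csd_records = study.records
    sites = _records_to_sites(csd_records)
    ev_rows, posteriors = [], []
    for (animal, hemi, env), csds in sorted(sites.items()):
        for tag in models:
            post = fit_recording(csds, tag, settings=settings,
                                 metadata={"animal": animal,
                                           "hemisphere": hemi,
                                           "environment": env})
            ev_rows.append({"animal": animal, "hemisphere": hemi,
                            "environment": env, "model": tag,
                            "log_evidence": post.free_energy,
                            "converged": post.converged})
            posteriors.append({"animal": animal, "hemisphere": hemi,
                               "environment": env, "model": tag,
                               "posterior": post})
            if progress:
                progress(animal, hemi, env, tag, post)
    return pd.DataFrame(ev_rows), posteriors


@dataclass
class StudyAnalysis:
    """Analysis products of one synthetic study."""

    evidence: pd.DataFrame             # per-recording log-evidences
    selection: dict                    # per environment -> SelectionResult
    effects: pd.DataFrame              # tidy MAP effect table (best model)
    dose_tests: pd.DataFrame           # group-level ANOVA / curve tests
    posteriors: list = field(repr=False, default_factory=list)


def analyse_study(study: StudyData, models=DEFAULT_MODELS,
                  settings: VLSettings | None = None,
                  var_order: int = 8) -> StudyAnalysis:
    """Invert, select the best architecture and run the dose statistics."""
    evidence, posteriors = invert_study(study, models, settings, var_order)
    selection = {}
    for env, ev_env in evidence.groupby("environment"):
        table = average_hemispheres(ev_env)
        selection[env] = select_model(table)
    best_overall = max(
        models,
        key=lambda m: evidence.loc[evidence["model"] == m,
                                   "log_evidence"].sum())
    best_records = [p for p in posteriors if p["model"] == best_overall]
    effects = build_effect_table(best_records)
    dose_tests = dose_test_table(effects)
    return StudyAnalysis(evidence=evidence, selection=selection,
                         effects=effects, dose_tests=dose_tests,
                         posteriors=posteriors)


def dose_test_table(effects: pd.DataFrame) -> pd.DataFrame:
    """Group-level dose statistics for every environment × region × param.

    Per cell: one-way ANOVA over dose levels, the overall direction test
    against baseline (decrease for H_e, increase for H_i and κ_i), and the
    dose-curve coefficient tests (negative linear slope for H_e; positive
    linear and negative quadratic coefficients for H_i).
    """
    rows = []
    for env in effects["environment"].unique():
        for region in ("A1", "PAF"):
            for param, direction in (("H_e", "less"), ("H_i", "greater"),
                                     ("kappa_i", "greater")):
                sel = effects[(effects["environment"] == env)
                              & (effects["region"] == region)
                              & (effects["param"] == param)]
                groups = [g["effect"].to_numpy()
                          for _, g in sel.groupby("dose")]
                anova = one_way_anova(groups)
                row = {"environment": env, "region": region, "param": param,
                       "anova_F": anova.F, "anova_df1": anova.df[0],
                       "anova_df2": anova.df[1], "anova_p": anova.p}
                try:
                    overall = overall_effect_test(effects, param, region,
                                                  env, direction)
                    row.update(overall_mean=overall.mean,
                               overall_sem=overall.sem, overall_p=overall.p)
                except SSRDCMError:
                    pass
                if param == "H_e":
                    curves = dose_response_curves(effects, param, region,
                                                  env, order=1)
                    t = group_coefficient_test(list(curves.values()),
                                               "slope", "less")
                    row.update(slope_mean=t.mean, slope_sem=t.sem,
                               slope_p=t.p)
                elif param == "H_i":
                    curves = dose_response_curves(effects, param, region,
                                                  env, order=2)
                    tq = group_coefficient_test(list(curves.values()),
                                                "quadratic", "less")
                    tl = group_coefficient_test(list(curves.values()),
                                                "slope", "greater")
                    row.update(quad_mean=tq.mean, quad_sem=tq.sem,
                               quad_p=tq.p, linear_mean=tl.mean,
                               linear_sem=tl.sem, linear_p=tl.p)
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunManifest:
    """Record of a pipeline run: stages, timing, outputs, config hash."""

    config_hash: str
    version: str
    stages: list = field(default_factory=list)

    def add(self, name, status, seconds, outputs):
        self.stages.append({"stage": name, "status": status,
                            "seconds": round(seconds, 3),
                            "outputs": [str(o) for o in outputs]})

    def save(self, path):
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash, "version": self.version,
             "stages": self.stages}, indent=1))


def run_pipeline(config: dict, out_dir, force: bool = False,
                 log=print) -> RunManifest:
    """File-based end-to-end run.

    ``config`` holds a ``study`` section (StudyConfig fields, seed
    mandatory), optional ``mode`` ("spectra"/"timeseries"), ``models`` and
    ``inversion`` (VLSettings fields).  Stages whose outputs already exist
    are skipped unless ``force``.  Failures are recorded in the manifest
    and abort downstream stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_io.config_hash(config),
                           version=__version__)
    mode = config.get("mode", "spectra")
    models = tuple(config.get("models", DEFAULT_MODELS))
    study_cfg = StudyConfig(**config.get("study", {}))
    settings = VLSettings(**config.get("inversion", {}))
    state = {}

    def stage(name, marker, fn):
        marker_path = out / marker
        t0 = time.perf_counter()
        if marker_path.exists() and not force:
            log(f"[{name}] up to date, skipping")
            manifest.add(name, "skipped", 0.0, [marker_path])
            return True
        try:
            outputs = fn()
        except Exception as exc:                     # localized failure
            log(f"[{name}] FAILED: {exc}")
            manifest.add(name, f"failed: {exc}", time.perf_counter() - t0, [])
            return False
        manifest.add(name, "ok", time.perf_counter() - t0,
                     outputs + [marker_path])
        log(f"[{name}] done in {time.perf_counter() - t0:.1f}s")
        return True

    def do_simulate():
        study = generate_study(study_cfg, mode=mode)
        state["study"] = study
        data_dir = out / "data"
        data_dir.mkdir(exist_ok=True)
        outputs = []
        for rec in study.records:
            if mode == "timeseries":
                sim = rec["series"]
                p = data_dir / f"{rec['id']}.tsv"
                _io.write_timeseries(p, sim.data, sim.channels, sim.fs,
                                     {k: rec[k] for k in
                                      ("animal", "hemisphere", "dose",
                                       "environment", "spawn_key")})
            else:
                p = data_dir / f"{rec['id']}.csd.json"
                _io.write_csd(p, rec["csd"])
            outputs.append(p)
        study.manifest.to_csv(out / "recordings.csv", index=False)
        study.truth.curve_frame().to_csv(out / "truth_curves.csv",
                                         index=False)
        (out / "simulate.done").write_text("ok")
        return outputs

    def do_invert():
        study = state.get("study")
        if study is None:
            study = generate_study(study_cfg, mode=mode)
            state["study"] = study
        analysis = analyse_study(study, models, settings)
        state["analysis"] = analysis
        post_dir = out / "posteriors"
        post_dir.mkdir(exist_ok=True)
        outputs = []
        for rec in analysis.posteriors:
            p = post_dir / (f"{rec['animal']}_{rec['hemisphere']}_"
                            f"{rec['environment']}_{rec['model']}.json")
            _io.write_posterior(p, rec["posterior"])
            outputs.append(p)
        analysis.evidence.to_csv(out / "evidence.csv", index=False)
        (out / "invert.done").write_text("ok")
        return outputs

    def ensure_analysis():
        """Rebuild the selection/effects products from disk after a skip."""
        if "analysis" in state:
            return state["analysis"]
        evidence = pd.read_csv(out / "evidence.csv")
        posteriors = []
        for p in sorted((out / "posteriors").glob("*.json")):
            post = _io.read_posterior(p)
            md = post.metadata
            posteriors.append({"animal": md["animal"],
                               "hemisphere": md["hemisphere"],
                               "environment": md["environment"],
                               "model": md["architecture"],
                               "posterior": post})
        selection = {}
        for env, ev_env in evidence.groupby("environment"):
            selection[env] = select_model(average_hemispheres(ev_env))
        best = max(models, key=lambda m: evidence.loc[
            evidence["model"] == m, "log_evidence"].sum())
        effects = build_effect_table(
            [p for p in posteriors if p["model"] == best])
        analysis = StudyAnalysis(evidence=evidence, selection=selection,
                                 effects=effects, dose_tests=pd.DataFrame(),
                                 posteriors=posteriors)
        state["analysis"] = analysis
        return analysis

    def do_compare():
        analysis = ensure_analysis()
        payload = {}
        for env, sel in analysis.selection.items():
            payload[env] = {
                "ranking": list(sel.ranking),
                "summed_evidence": sel.summed_evidence,
                "ln_gbf": {f"{a}>{b}": v
                           for (a, b), v in sel.pairwise_ln_gbf.items()},
                "labels": {f"{a}>{b}": v
                           for (a, b), v in sel.labels.items()},
                "tied": sel.tied,
            }
        p = out / "selection.json"
        p.write_text(json.dumps(payload, indent=1))
        (out / "compare.done").write_text("ok")
        return [p]

    def do_dose():
        analysis = ensure_analysis()
        if analysis.dose_tests.empty:
            analysis.dose_tests = dose_test_table(analysis.effects)
        analysis.effects.to_csv(out / "effects.csv", index=False)
        analysis.dose_tests.to_csv(out / "dose_tests.csv", index=False)
        (out / "dose.done").write_text("ok")
        return [out / "effects.csv", out / "dose_tests.csv"]

    ok = stage("simulate", "simulate.done", do_simulate)
    if ok:
        ok = stage("invert", "invert.done", do_invert)
    if ok:
        stage("compare", "compare.done", do_compare)
        stage("dose", "dose.done", do_dose)
    manifest.save(out / "run_manifest.json")
    return manifest
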