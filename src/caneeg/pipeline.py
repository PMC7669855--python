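"""Seeded end-to-end runs: configuration, stage orchestration, artifacts.

A :class:`RunConfig` bundles every stage parameter with the study's values
as defaults (2–40 / 2–25 Hz bands, 100 / 50 uV rejection, 20-ms bins,
10-fold CV, 200 permutations, alpha 0.05, Bonferroni over 8 subjects).
:func:`run_pipeline` executes the selected stages in dependency order on an
artifact directory; every result table is CSV with a header comment
carrying the config hash and master seed, so identical config + seed give
identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation, decoding, dipole, erp, permutation, preprocessing
from .epochs import EpochsSet, load_epochs, save_epochs
from .labels import ALL_CATEGORIES, FACE_CATEGORIES
from .simulate import ComponentSpec, SimulationConfig, default_components

log = logging.getLogger("caneeg")

STAGES = ("simulate", "preprocess", "erp", "decode", "permute", "aggregate", "dipole")


@dataclass
class RunConfig:
    """Every stage's parameters plus paths and the master seed."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple = STAGES
    seed: int = 0
    # ERP stream
    erp_band_hz: tuple = (2.0, 40.0)
    reject_uV: float = 100.0
    reject_window_ms: tuple = (-150.0, 350.0)
    baseline_ms: tuple = (-150.0, 0.0)
    anova_range_ms: tuple = (0.0, 250.0)
    anova_window_ms: float = 16.0
    anova_step_ms: float = 4.0
    anova_alpha: float = 0.05
    anova_min_run: int = 2
    # decoding stream
    decoding_band_hz: tuple = (2.0, 25.0)
    bin_width_ms: float = 20.0
    n_folds: int = 10
    svm_C: float = 1.0
    classifier: str = "svm"
    standardize: bool = True
    timecourse_range_ms: tuple | None = None  # default: whole binned epoch
    # permutation inference
    n_perm: int = 200
    perm_alpha: float = 0.05
    bonferroni_n: int | None = None  # default: n_subjects
    # source modelling
    dipole_window_ms: tuple = (90.0, 110.0)
    dipole_band_hz: tuple = (2.0, 25.0)
    dipole_reject_uV: float = 50.0
    dipole_grid_mm: float = 2.0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.simulation.validate()
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["components"] = [
            {**dataclasses.asdict(c), "categories": [str(x) for x in c.categories]}
            for c in self.simulation.components
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "components" in sim:
            sim["components"] = tuple(
                ComponentSpec(
                    latency_ms=c["latency_ms"],
                    width_ms=c["width_ms"],
                    amplitude=dict(c["amplitude"]),
                    categories=tuple(c["categories"]),
                    name=c.get("name", ""),
                )
                for c in sim["components"]
            )
        for key in ("trials_per_condition", "epoch_span_ms", "channels"):
            if key in sim:
                sim[key] = tuple(sim[key])
        d["simulation"] = SimulationConfig(**sim)
        for key, value in list(d.items()):
            if isinstance(value, list):
                d[key] = tuple(value)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict())))

    def config_hash(self) -> str:
        blob = json.dumps(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def demo_config(seed: int = 0) -> RunConfig:
    """A minutes-scale configuration exercising every stage end to end."""
    sim = SimulationConfig(
        n_subjects=2,
        trials_per_condition=(12, 14),
        epoch_span_ms=(-150.0, 350.0),
        components=tuple(default_components()),
        seed=seed,
    )
    return RunConfig(
        simulation=sim,
        seed=seed,
        n_folds=5,
        n_perm=20,
        timecourse_range_ms=(0.0, 200.0),
        dipole_grid_mm=5.0,
    )


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# caneeg config={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a pipeline CSV artifact, skipping the provenance header."""
    return pd.read_csv(path, comment="#")


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def _subject_paths(outdir: Path) -> list:
    return sorted(outdir.glob("epochs/*.json"))


def stage_simulate(config: RunConfig, outdir: Path) -> list:
    from .simulate import generate_experiment

    sim = dataclasses.replace(config.simulation, seed=config.seed)
    subjects = generate_experiment(sim)
    for ep in subjects:
        save_epochs(ep, outdir / "epochs" / ep.subject)
        log.info("simulate: subject %s, %d trials", ep.subject, ep.n_trials)
    return subjects


def _load_subjects(outdir: Path) -> list:
    paths = _subject_paths(outdir)
    if not paths:
        raise PipelineError("no epochs found; run the simulate stage first")
    return [load_epochs(p.with_suffix("")) for p in paths]


def _erp_epochs(config: RunConfig, ep: EpochsSet) -> EpochsSet:
    return preprocessing.erp_stream(
        ep,
        band=config.erp_band_hz,
        reject_uV=config.reject_uV,
        reject_window_ms=config.reject_window_ms,
        baseline_ms=config.baseline_ms,
    )


def _decoding_epochs(config: RunConfig, ep: EpochsSet) -> EpochsSet:
    return preprocessing.decoding_stream(
        ep, band=config.decoding_band_hz, bin_width_ms=config.bin_width_ms
    )


def stage_preprocess(config: RunConfig, outdir: Path) -> None:
    rows = []
    for ep in _load_subjects(outdir):
        clean = _erp_epochs(config, ep)
        dev = preprocessing.amplitude_deviations(ep, config.reject_window_ms)
        dev.insert(0, "subject", ep.subject)
        dev["rejected"] = ~clean.kept[dev["trial"].to_numpy()]
        rows.append(dev)
        log.info(
            "preprocess: %s kept %d/%d trials", ep.subject,
            int(clean.kept.sum()), clean.n_trials,
        )
    _write_table(pd.concat(rows, ignore_index=True),
                 outdir / "rejection_report.csv", config)


def stage_erp(config: RunConfig, outdir: Path) -> dict:
    subjects = _load_subjects(outdir)
    evokeds, face_ev, obj_ev = [], [], []
    for ep in subjects:
        clean = _erp_epochs(config, ep)
        evokeds.append({c: erp.average_evoked(clean, c) for c in FACE_CATEGORIES})
        face_ev.append(erp.average_evoked(clean, FACE_CATEGORIES))
        obj_ev.append(erp.average_evoked(clean, "OB"))
    stats = erp.sliding_window_anova(
        evokeds,
        range_ms=config.anova_range_ms,
        window_ms=config.anova_window_ms,
        step_ms=config.anova_step_ms,
    )
    windows = erp.contiguity_filter(stats, config.anova_alpha, config.anova_min_run)
    contrast = erp.sliding_contrast(
        face_ev, obj_ev,
        range_ms=config.anova_range_ms,
        window_ms=config.anova_window_ms,
        step_ms=config.anova_step_ms,
    )
    _write_table(stats, outdir / "erp_anova.csv", config)
    _write_table(windows, outdir / "erp_significant_windows.csv", config)
    _write_table(contrast, outdir / "erp_contrast_face_object.csv", config)
    log.info("erp: %d windows tested, %d reported runs", len(stats), len(windows))
    return {"anova": stats, "windows": windows, "contrast": contrast}


def _timecourse_intervals(config: RunConfig, binned: EpochsSet) -> list:
    if config.timecourse_range_ms is None:
        return list(range(binned.n_samples))
    t0, t1 = config.timecourse_range_ms
    return [
        k for k, s in enumerate(binned.times)
        if t0 <= s and s + config.bin_width_ms <= t1 + 1e-9
    ]


def stage_decode(config: RunConfig, outdir: Path) -> dict:
    subjects = _load_subjects(outdir)
    whole_rows, tc_rows = [], []
    for ep in subjects:
        binned = _decoding_epochs(config, ep)
        feats = preprocessing.vectorize_features(binned, "whole-epoch")
        for task in decoding.enumerate_tasks(ALL_CATEGORIES, subject=ep.subject):
            res = decoding.crossval_accuracy(
                feats, task.pair, config.n_folds, config.classifier,
                config.svm_C, config.standardize, seed=config.seed,
            )
            whole_rows.append(_result_row(res, interval_start=np.nan))
        intervals = _timecourse_intervals(config, binned)
        for task in decoding.scrambled_tasks(subject=ep.subject):
            for res in decoding.timecourse_accuracies(
                binned, task.pair, config.n_folds, config.classifier,
                config.svm_C, config.standardize, seed=config.seed,
                intervals=intervals,
            ):
                tc_rows.append(
                    _result_row(res, interval_start=binned.times[res.task.interval_index])
                )
        log.info("decode: %s done", ep.subject)
    whole = pd.DataFrame(whole_rows)
    tc = pd.DataFrame(tc_rows)
    _write_table(whole, outdir / "decoding_whole_epoch.csv", config)
    _write_table(tc, outdir / "decoding_timecourse.csv", config)
    return {"whole": whole, "timecourse": tc}


def _result_row(res: decoding.ClassificationResult, interval_start: float) -> dict:
    return {
        "subject": res.task.subject,
        "task": res.task.name,
        "mode": res.task.mode,
        "interval_index": res.task.interval_index,
        "interval_start_ms": interval_start,
        "accuracy": res.accuracy,
        "n_folds": len(res.fold_accuracies),
        "n_class_a": list(res.n_per_class.values())[0],
        "n_class_b": list(res.n_per_class.values())[1],
        "seed": res.seed,
    }


def stage_permute(config: RunConfig, outdir: Path) -> dict:
    subjects = _load_subjects(outdir)
    tc = read_table(outdir / "decoding_timecourse.csv")
    observed_by_subject, nulls_by_subject = {}, {}
    task_names, interval_starts = None, None
    for ep in subjects:
        binned = _decoding_epochs(config, ep)
        intervals = _timecourse_intervals(config, binned)
        tasks = decoding.scrambled_tasks(subject=ep.subject)
        nulls = []
        for ti, task in enumerate(tasks):
            nulls.extend(
                permutation.permutation_null_timecourse(
                    binned, task.pair, intervals, config.n_perm,
                    config.n_folds, config.classifier, config.svm_C,
                    config.standardize, seed=config.seed, task_index=ti,
                )
            )
        nulls_by_subject[ep.subject] = nulls
        sub = tc[tc["subject"] == ep.subject]
        obs = (
            sub.pivot(index="task", columns="interval_index", values="accuracy")
            .loc[[t.name for t in tasks], intervals]
            .to_numpy()
        )
        observed_by_subject[ep.subject] = obs
        task_names = [t.name for t in tasks]
        interval_starts = binned.times[intervals]
        log.info("permute: %s, %d nulls x %d permutations",
                 ep.subject, len(nulls), config.n_perm)
    bonf = config.bonferroni_n or len(subjects)
    matrix = permutation.build_significance_matrix(
        observed_by_subject, nulls_by_subject, task_names, interval_starts,
        alpha=config.perm_alpha, bonferroni_n=bonf,
    )
    chance = permutation.empirical_chance_interval(
        [n for nn in nulls_by_subject.values() for n in nn]
    )
    long = _matrix_to_long(matrix)
    _write_table(long, outdir / "significance_matrix.csv", config)
    _write_table(
        pd.DataFrame(
            {
                "subject": matrix.subjects,
                "threshold": matrix.thresholds,
                "alpha": matrix.alpha,
                "bonferroni_n": matrix.bonferroni_n,
                "chance_low_pct": chance[0],
                "chance_high_pct": chance[1],
            }
        ),
        outdir / "thresholds.csv", config,
    )
    return {"matrix": matrix, "chance": chance}


def _matrix_to_long(matrix: permutation.SignificanceMatrix) -> pd.DataFrame:
    ns, nt, ni = matrix.significant.shape
    return pd.DataFrame(
        {
            "subject": np.repeat(matrix.subjects, nt * ni),
            "task": np.tile(np.repeat(matrix.task_names, ni), ns),
            "interval_start_ms": np.tile(matrix.interval_starts_ms, ns * nt),
            "significant": matrix.significant.ravel().astype(int),
            "threshold": np.repeat(matrix.thresholds, nt * ni),
        }
    )


def _matrix_from_long(long: pd.DataFrame, alpha: float, bonferroni_n: int):
    subjects = sorted(long["subject"].unique())
    tasks = list(dict.fromkeys(long["task"]))
    intervals = np.sort(long["interval_start_ms"].unique())
    sig = np.zeros((len(subjects), len(tasks), len(intervals)), dtype=bool)
    thr = np.zeros(len(subjects))
    for i, s in enumerate(subjects):
        sub = long[long["subject"] == s]
        thr[i] = sub["threshold"].iloc[0]
        piv = sub.pivot(index="task", columns="interval_start_ms", values="significant")
        sig[i] = piv.loc[tasks, intervals].to_numpy().astype(bool)
    return permutation.SignificanceMatrix(
        significant=sig, subjects=subjects, task_names=tasks,
        interval_starts_ms=intervals, thresholds=thr,
        alpha=alpha, bonferroni_n=bonferroni_n,
    )


def stage_aggregate(config: RunConfig, outdir: Path) -> dict:
    long = read_table(outdir / "significance_matrix.csv")
    bonf = config.bonferroni_n or long["subject"].nunique()
    matrix = _matrix_from_long(long, config.perm_alpha, bonf)
    tc = aggregation.significant_fraction_timecourse(matrix)
    div_rows = [
        aggregation.division_fractions(matrix, division)
        for division in aggregation.standard_divisions().values()
    ]
    divisions = pd.concat(div_rows, ignore_index=True)
    _write_table(tc, outdir / "aggregate_timecourse.csv", config)
    _write_table(divisions, outdir / "aggregate_divisions.csv", config)
    return {"timecourse": tc, "divisions": divisions}


def stage_dipole(config: RunConfig, outdir: Path) -> dict:
    subjects = _load_subjects(outdir)
    model = dipole.SphereHeadModel()
    layout = dipole.default_canine_layout(model)
    # source stream: 2-25 Hz, 50 uV rejection, faces pooled, first subject
    ep = subjects[0]
    filtered = preprocessing.bandpass_filter(ep, *config.dipole_band_hz)
    filtered = preprocessing.reject_by_amplitude(
        filtered, config.dipole_reject_uV, config.reject_window_ms
    )
    filtered = preprocessing.baseline_correct(filtered, config.baseline_ms)
    evoked = erp.average_evoked(filtered, FACE_CATEGORIES)
    fits = dipole.fit_ecd_window(
        evoked, config.dipole_window_ms, model=model, layout=layout,
        grid_spacing_mm=config.dipole_grid_mm,
    )
    fit_df = pd.DataFrame(
        {
            "time_ms": [f.time_ms for f in fits],
            "x_mm": [f.location_mm[0] for f in fits],
            "y_mm": [f.location_mm[1] for f in fits],
            "z_mm": [f.location_mm[2] for f in fits],
            "qx_nAm": [f.moment_nAm[0] for f in fits],
            "qy_nAm": [f.moment_nAm[1] for f in fits],
            "qz_nAm": [f.moment_nAm[2] for f in fits],
            "moment_nAm": [f.moment_magnitude_nAm for f in fits],
            "gof_percent": [f.gof_percent for f in fits],
        }
    )
    best = fits[int(np.argmax([f.moment_magnitude_nAm for f in fits]))]
    tcourse = dipole.moment_timecourse(
        evoked, best.location_mm, model, layout,
        window_ms=(max(-50.0, evoked.times[0]), min(300.0, evoked.times[-1])),
    )
    _write_table(fit_df, outdir / "dipole_fits.csv", config)
    _write_table(tcourse, outdir / "dipole_timecourse.csv", config)
    log.info("dipole: %d fits, best |q|=%.1f nAm GOF=%.1f%%",
             len(fits), best.moment_magnitude_nAm, best.gof_percent)
    return {"fits": fit_df, "timecourse": tcourse}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "erp": stage_erp,
    "decode": stage_decode,
    "permute": stage_permute,
    "aggregate": stage_aggregate,
    "dipole": stage_dipole,
}


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the selected stages in dependency order.

    Stage failures abort the run with the failing stage named. Returns the
    artifact directory.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        config.to_yaml(outdir / "run_config.yaml")
        log.info("run: config=%s seed=%d stages=%s",
                 config.config_hash(), config.seed, ",".join(config.stages))
        for stage in STAGES:
            if stage not in config.stages:
                continue
            try:
                _STAGE_FUNCS[stage](config, outdir)
            except Exception as exc:
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return outdir
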