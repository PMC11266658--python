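"""Pipeline orchestration: simulate -> segment -> fit -> report.

One :class:`RunConfig` drives the whole chain with a single master seed;
every stage persists its intermediates (traces.csv, periods.csv, fits.json,
bootstrap.csv) so any stage can be re-run from the previous stage's files
and yield identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .segment import (
    BleachDetrender,
    ChangePointSegmenter,
    ModeBackgroundSubtractor,
    extract_periods,
    tune_cpd,
)
from .simulate import (
    SCENARIO_PRESETS,
    FourStateScenario,
    ObservationParams,
    synthesize_cohort,
)
from .survival import (
    bootstrap_fits,
    burst_run_stats,
    fit_biexponential,
    fit_exponential_censored,
)

__all__ = ["RunConfig", "StrainReport", "run_pipeline", "compare_strains",
            "segment_cohort", "fit_periods", "load_traces_csv"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (one strain)."""

    mode: str = "simulate"              # simulate | traces
    scenario: str | dict = "wildtype_like"
    n_cells: int = 200
    seed: int = 0
    traces_path: str | None = None      # for mode="traces"
    observation: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    fit: dict = field(default_factory=lambda: {"bootstrap": 300, "t_probe": 0.01,
                                               "constrained": True})
    out_dir: str | None = None

    def __post_init__(self):
        if self.mode not in ("simulate", "traces"):
            raise ValueError("mode must be 'simulate' or 'traces'")
        if self.mode == "traces" and not self.traces_path:
            raise ValueError("mode='traces' requires traces_path")
        if self.mode == "simulate" and self.n_cells < 1:
            raise ValueError("empty cohort: n_cells must be >= 1")

    def scenario_obj(self) -> FourStateScenario:
        if isinstance(self.scenario, str):
            if self.scenario not in SCENARIO_PRESETS:
                raise ValueError(f"unknown scenario preset {self.scenario!r}")
            return SCENARIO_PRESETS[self.scenario]()
        return FourStateScenario(**self.scenario)

    def observation_obj(self) -> ObservationParams:
        return ObservationParams(**self.observation)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        doc = dataclasses.asdict(self)
        doc.pop("out_dir", None)
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StrainReport:
    """Strain-level summary of period statistics and fits."""

    strain: str
    n_cells: int
    seed: int
    config_digest: str
    window: float
    frame_interval: float
    n_periods: dict
    internal_on: dict
    internal_off: dict
    external_off: dict
    burst_runs: dict
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)

    def render(self) -> str:
        lines = [
            f"strain {self.strain}  ({self.n_cells} cells, seed {self.seed}, "
            f"config {self.config_digest})",
            f"  periods: {self.n_periods}",
            f"  internal ON : mu = {self.internal_on.get('mu_boot_mean', float('nan')):.1f}"
            f" +/- {self.internal_on.get('mu_boot_sd', float('nan')):.1f} s,"
            f" class = {self.internal_on.get('classification')},"
            f" f({self.internal_on.get('t_probe')}) = "
            f"{self.internal_on.get('f_probe_mean', float('nan')):.4g}"
            f" +/- {self.internal_on.get('f_probe_sd', float('nan')):.4g}",
            f"  internal OFF: mean = {self.internal_off.get('mean', float('nan')):.1f} s,"
            f" class = {self.internal_off.get('classification')}",
            f"  external OFF: mu = {self.external_off.get('mu', float('nan')):.0f} s"
            f" (n_obs {self.external_off.get('n_observed')},"
            f" n_cens {self.external_off.get('n_censored')})",
            f"  burst runs  : p_long = {self.burst_runs.get('p_long', float('nan')):.3f}"
            f" (n {self.burst_runs.get('n')})",
        ]
        return "\n".join(lines)


def load_traces_csv(path) -> np.ndarray:
    """Intensity matrix from a (cell, frame, time_s, intensity) table."""
    df = pd.read_csv(path)
    mat = df.pivot_table(index="cell", columns="frame", values="intensity")
    return mat.to_numpy(float)


def segment_cohort(X: np.ndarray, frame_interval: float = 2.5,
                   seg_cfg: dict | None = None):
    """Preprocess and segment an intensity matrix into a period table.

    Returns ``(periods, labels, info)``: the per-cell period table, the
    binary ON/OFF frame matrix, and a dict of stage diagnostics.
    """
    cfg = dict(seg_cfg or {})
    do_tune = cfg.pop("tune", False)
    det = BleachDetrender(frame_interval=frame_interval)
    X1 = det.fit_transform(X)
    X2 = ModeBackgroundSubtractor().fit_transform(X1)
    if do_tune:
        params, diag = tune_cpd(X2, frame_interval=frame_interval)
        cfg.setdefault("half_window", params.half_window)
        cfg.setdefault("threshold", params.threshold)
        cfg.setdefault("min_size", params.min_size)
    seg = ChangePointSegmenter(**{k: v for k, v in cfg.items()
                                  if k in ("half_window", "threshold",
                                           "min_size", "label_frac",
                                           "random_state")})
    labels = seg.fit_predict(X2)
    periods = pd.concat(
        [extract_periods(labels[i], frame_interval, cell=i)
         for i in range(labels.shape[0])],
        ignore_index=True,
    )
    info = {"bleach_rate": det.rate_, "half_window": seg.half_window,
            "threshold": seg.threshold, "min_size": seg.min_size}
    return periods, labels, info


def fit_periods(periods: pd.DataFrame, window: float, frame_interval: float,
                fit_cfg: dict | None = None, seed: int = 0,
                duration_floor: float | None = None) -> dict:
    """Survival fits and burst-run statistics from a period table.

    ``duration_floor`` defaults to the shortest measurable period in the
    table (the segmentation resolution); the bootstrap fits in shifted time
    to undo the left-truncation bias (see :func:`bootstrap_fits`).
    """
    cfg = dict(fit_cfg or {})
    B = int(cfg.get("bootstrap", 300))
    t_probe = float(cfg.get("t_probe", 0.01))
    constrained = bool(cfg.get("constrained", True))
    if duration_floor is None:
        internal = periods[periods["class"] == "internal"]
        duration_floor = float(internal["duration_s"].min()) if len(internal) else 0.0

    out: dict = {}
    ion = periods[(periods["label"] == "ON") & (periods["class"] == "internal")]
    ioff = periods[(periods["label"] == "OFF") & (periods["class"] == "internal")]
    out["n_periods"] = {
        "internal_ON": int(len(ion)),
        "internal_OFF": int(len(ioff)),
        "external_OFF": int(((periods["label"] == "OFF")
                             & (periods["class"] != "internal")).sum()),
    }

    fit_on = fit_biexponential(ion["duration_s"].to_numpy(), constrained=constrained)
    bs = bootstrap_fits(periods, B=B, t_probe=t_probe, seed=seed,
                        label="ON", weak_peak_time=frame_interval,
                        duration_floor=duration_floor)
    lam1_bag = float(bs.replicates["lambda1"].median())
    lam2_bag = float(bs.replicates["lambda2"].median())
    out["internal_on"] = {
        "a": fit_on.a, "lambda1": fit_on.lambda1, "lambda2": fit_on.lambda2,
        "c1": fit_on.c1, "c2": fit_on.c2, "f0": fit_on.f0,
        "lambda1_boot_median": lam1_bag, "lambda2_boot_median": lam2_bag,
        "classification": fit_on.classify(weak_peak_time=frame_interval),
        "mean": fit_on.mean(), "sample_mean": float(ion["duration_s"].mean()),
        "t_probe": t_probe, "f_probe_mean": bs.f_probe_mean,
        "f_probe_sd": bs.f_probe_sd, "mu_boot_mean": bs.mu_mean,
        "mu_boot_sd": bs.mu_sd, "fractions": bs.fractions,
    }

    out["internal_off"] = {"n": int(len(ioff))}
    if len(ioff) >= 30:
        fit_off = fit_biexponential(ioff["duration_s"].to_numpy(),
                                    constrained=constrained)
        out["internal_off"].update(
            {"a": fit_off.a, "lambda1": fit_off.lambda1,
             "lambda2": fit_off.lambda2, "f0": fit_off.f0,
             "classification": fit_off.classify(weak_peak_time=frame_interval)}
        )
    out["internal_off"]["mean"] = float(ioff["duration_s"].mean()) if len(ioff) else float("nan")

    try:
        ext = fit_exponential_censored(periods, window=window)
        out["external_off"] = {"mu": ext.mu, "lambda": ext.lam,
                               "n_observed": ext.n_observed,
                               "n_censored": ext.n_censored}
    except ValueError as err:
        out["external_off"] = {"error": str(err)}

    try:
        out["burst_runs"] = burst_run_stats(periods)
    except ValueError as err:
        out["burst_runs"] = {"error": str(err)}

    out["bootstrap_replicates"] = bs.replicates
    return out


def run_pipeline(cfg: RunConfig) -> StrainReport:
    """Execute simulate -> segment -> fit and build the strain report.

    With ``cfg.out_dir`` set, intermediates are persisted: traces.csv,
    truth_periods.csv, scenario.json (simulate), periods.csv (segment),
    fits.json / bootstrap.csv / report.json / report.txt (fit, report).
    Identical config + seed give identical outputs.
    """
    ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    obs = cfg.observation_obj()
    if cfg.mode == "simulate":
        scen = cfg.scenario_obj()
        cohort = synthesize_cohort(scen, obs, cfg.n_cells, stage_seeds[0])
        X = cohort.intensity_matrix()
        strain = scen.strain
        if out:
            cohort.traces_frame().to_csv(out / "traces.csv", index=False)
            cohort.truth_periods.to_csv(out / "truth_periods.csv", index=False)
            (out / "scenario.json").write_text(
                json.dumps(dataclasses.asdict(scen), indent=2)
            )
    else:
        X = load_traces_csv(cfg.traces_path)
        strain = Path(cfg.traces_path).stem

    periods, labels, seg_info = segment_cohort(X, obs.frame_interval, cfg.segment)
    if out:
        periods.to_csv(out / "periods.csv", index=False)

    fits = fit_periods(periods, obs.window, obs.frame_interval, cfg.fit,
                       seed=stage_seeds[2])
    boot = fits.pop("bootstrap_replicates")
    if out:
        boot.to_csv(out / "bootstrap.csv", index=False)
        (out / "fits.json").write_text(json.dumps(fits, indent=2, default=float))

    report = StrainReport(
        strain=strain,
        n_cells=int(X.shape[0]),
        seed=cfg.seed,
        config_digest=cfg.digest(),
        window=obs.window,
        frame_interval=obs.frame_interval,
        n_periods=fits["n_periods"],
        internal_on=fits["internal_on"],
        internal_off=fits["internal_off"],
        external_off=fits["external_off"],
        burst_runs=fits["burst_runs"],
    )
    if out:
        (out / "report.json").write_text(report.to_json())
        (out / "report.txt").write_text(report.render() + "\n")
    return report


def compare_strains(reports: list) -> pd.DataFrame:
    """Side-by-side comparison table of strain reports.

    Refuses to compare runs with different observation geometry.  No
    inferential statistics beyond the bootstrap SDs carried in the reports.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    geo = {(r.window, r.frame_interval) for r in reports}
    if len(geo) > 1:
        raise ValueError("mismatched window/frame interval across reports")
    rows = []
    for r in reports:
        rows.append(
            {
                "strain": r.strain,
                "n_cells": r.n_cells,
                "mu_external_off_s": r.external_off.get("mu", float("nan")),
                "mean_internal_on_s": r.internal_on.get("sample_mean", float("nan")),
                "mean_internal_off_s": r.internal_off.get("mean", float("nan")),
                "classification_on": r.internal_on.get("classification"),
                "f0_on": r.internal_on.get("f0", float("nan")),
                "p_long": r.burst_runs.get("p_long", float("nan")),
            }
        )
    return pd.DataFrame(rows)
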