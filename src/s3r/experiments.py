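"""Orchestrated in-silico validation studies.

Three studies run the full pipeline (sample -> crust -> spherize -> virtual
10/20 measurement) against ground-truth landmarks measured directly on a
dense head model:

* sample-size sweep: mean landmark error (ME) versus sample size, with a
  power-law fit and the fraction of runs under the 3 mm accuracy criterion;
* uniformness study: repeated fixed-size sampling, correlating the
  uniformness index (UI) with ME;
* cap study: EEG-cap perturbed sampling (0-13 mm), repeated, reporting
  per-landmark Error and Variance.

All studies are deterministic given (config, master seed): run seeds are
derived as master + run index (mod 2^31).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .head_model import HeadModel
from .metrics import (
    RepeatStats,
    fit_power_law,
    landmark_errors,
    pearson_correlation,
    repeat_stats,
)
from .reconstruct import ReconstructionError, crust_reconstruct, spherize
from .sampling_sim import (
    PerturbationRule,
    SamplingRule,
    cap_perturb,
    uniform_sample,
    uniformness_index,
)
from .virtual_1020 import LandmarkSet, measure_105_grid, measure_1020

__all__ = [
    "SweepConfig",
    "StudyReport",
    "ground_truth_1020",
    "reconstruct_and_measure",
    "run_size_sweep",
    "run_uniformness_study",
    "run_cap_study",
]


@dataclass
class SweepConfig:
    sizes: tuple = tuple(range(10, 111))
    repeats: int = 20
    seed: int = 0
    levels: int = 5

    def __post_init__(self):
        if min(self.sizes) < 10:
            raise ValueError("sample sizes must be >= 10")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class StudyReport:
    study: str
    config: dict
    records: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_json(self, path=None) -> str:
        payload = {
            "study": self.study,
            "version": __version__,
            "config": self.config,
            "summary": self.summary,
            "records": self.records,
        }
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _run_seed(master: int, index: int) -> int:
    return int((master + index) % 2**31)


_TRUTH_CACHE: dict[int, LandmarkSet] = {}


def ground_truth_1020(head: HeadModel) -> LandmarkSet:
    """10/20 landmarks measured directly on the full-resolution head model
    (cached per head object)."""
    key = id(head)
    if key not in _TRUTH_CACHE:
        _TRUTH_CACHE[key] = measure_1020(head.surface, head.refs)
    return _TRUTH_CACHE[key]


def reconstruct_and_measure(cloud, levels: int = 5) -> LandmarkSet:
    """The S3R_VM pipeline on one sample cloud: crust, spherize, measure."""
    crust = crust_reconstruct(cloud)
    dense = spherize(crust, levels=levels)
    return measure_1020(dense.surface, cloud.refs)


def run_size_sweep(head: HeadModel, cfg: SweepConfig) -> StudyReport:
    """ME versus sample size, each size repeated ``cfg.repeats`` times."""
    truth = ground_truth_1020(head)
    grid = measure_105_grid(head.surface, head.refs)
    records = []
    run_idx = 0
    for size in cfg.sizes:
        for rep in range(cfg.repeats):
            seed = _run_seed(cfg.seed, run_idx)
            run_idx += 1
            rec = {"size": int(size), "repeat": rep, "seed": seed}
            try:
                cloud = uniform_sample(grid, SamplingRule(n=size, seed=seed))
                est = reconstruct_and_measure(cloud, levels=cfg.levels)
                rec["me"] = landmark_errors(est, truth).me
                rec["ok"] = True
            except (ReconstructionError, RuntimeError, ValueError) as exc:
                rec["ok"] = False
                rec["error"] = str(exc)
            records.append(rec)

    ok = [r for r in records if r["ok"]]
    sizes = [r["size"] for r in ok]
    mes = [r["me"] for r in ok]
    fit = fit_power_law(sizes, mes) if len(ok) >= 3 else None
    by_size = {}
    for s in sorted(set(sizes)):
        vals = np.array([r["me"] for r in ok if r["size"] == s])
        by_size[int(s)] = {
            "mean_me": float(vals.mean()),
            "sd_me": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "frac_me_below_3mm": float((vals < 3.0).mean()),
            "n": int(len(vals)),
        }
    summary = {
        "n_runs": len(records),
        "n_failed": len(records) - len(ok),
        "by_size": by_size,
        "power_fit": None
        if fit is None
        else {"a": fit.a, "b": fit.b, "r_squared": fit.r_squared},
    }
    return StudyReport(
        study="size_sweep",
        config={"sizes": list(cfg.sizes), "repeats": cfg.repeats, "seed": cfg.seed,
                "levels": cfg.levels, "head": head.label},
        records=records,
        summary=summary,
    )


def run_uniformness_study(
    head: HeadModel, n: int = 21, repeats: int = 100, seed: int = 0, levels: int = 5
) -> StudyReport:
    """Repeated fixed-size sampling; reports UI and ME per repeat and their
    Pearson correlation."""
    truth = ground_truth_1020(head)
    grid = measure_105_grid(head.surface, head.refs)
    records = []
    for rep in range(repeats):
        run_seed = _run_seed(seed, rep)
        rec = {"repeat": rep, "seed": run_seed}
        try:
            cloud = uniform_sample(grid, SamplingRule(n=n, seed=run_seed))
            crust = crust_reconstruct(cloud)
            rec["ui"] = uniformness_index(cloud, crust=crust)
            dense = spherize(crust, levels=levels)
            est = measure_1020(dense.surface, cloud.refs)
            rec["me"] = landmark_errors(est, truth).me
            rec["ok"] = True
        except (ReconstructionError, RuntimeError, ValueError) as exc:
            rec["ok"] = False
            rec["error"] = str(exc)
        records.append(rec)

    ok = [r for r in records if r["ok"] and np.isfinite(r["ui"])]
    summary = {"n_runs": repeats, "n_failed": repeats - sum(r["ok"] for r in records)}
    if len(ok) >= 3:
        r, p = pearson_correlation([r_["ui"] for r_ in ok], [r_["me"] for r_ in ok])
        mes = np.array([r_["me"] for r_ in ok])
        summary.update(
            {
                "pearson_r": r,
                "pearson_p": p,
                "mean_me": float(mes.mean()),
                "sd_me": float(mes.std(ddof=1)),
            }
        )
    return StudyReport(
        study="uniformness",
        config={"n": n, "repeats": repeats, "seed": seed, "levels": levels,
                "head": head.label},
        records=records,
        summary=summary,
    )


def run_cap_study(
    head: HeadModel,
    repeats: int = 20,
    max_dist: float = 13.0,
    seed: int = 0,
    levels: int = 5,
) -> StudyReport:
    """EEG-cap perturbation study: sample the 21 landmarks with 0-13 mm
    on-surface noise, rerun the pipeline, report per-landmark Error and
    Variance (Table-style) plus per-repeat ME."""
    truth = ground_truth_1020(head)
    records = []
    estimates: list[LandmarkSet] = []
    for rep in range(repeats):
        run_seed = _run_seed(seed, rep)
        rec = {"repeat": rep, "seed": run_seed}
        try:
            cloud = cap_perturb(
                truth, head.surface, PerturbationRule(max_distance=max_dist, seed=run_seed),
                refs=head.refs,
            )
            est = reconstruct_and_measure(cloud, levels=levels)
            estimates.append(est)
            rec["me"] = landmark_errors(est, truth).me
            rec["ok"] = True
        except (ReconstructionError, RuntimeError, ValueError) as exc:
            rec["ok"] = False
            rec["error"] = str(exc)
        records.append(rec)

    summary: dict = {"n_runs": repeats, "n_failed": repeats - len(estimates)}
    if len(estimates) >= 2:
        stats_by_lm: dict[str, RepeatStats] = repeat_stats(estimates, truth)
        table = [
            {"landmark": name, "error": st.error, "variance": st.variance}
            for name, st in stats_by_lm.items()
        ]
        summary["per_landmark"] = table
        summary["mean_error"] = float(np.mean([row["error"] for row in table]))
        summary["mean_variance"] = float(np.mean([row["variance"] for row in table]))
    return StudyReport(
        study="cap_perturbation",
        config={"repeats": repeats, "max_dist": max_dist, "seed": seed,
                "levels": levels, "head": head.label},
        records=records,
        summary=summary,
    )
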