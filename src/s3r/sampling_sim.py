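"""Simulators of how an experimenter samples the scalp.

* ``uniform_sample`` draws a roughly uniform sparse sample from the
  5 %-resolution candidate grid under four constraints: candidates only, all
  points unique, at least one per region subset, and subset counts differing
  by at most one.
* ``cap_perturb`` emulates EEG-cap-guided sampling: each of the 21 landmarks
  is replaced by a random on-surface neighbour within 0-13 mm, the typical
  cap placement error.
* ``uniformness_index`` (UI) quantifies sampling uniformity as the
  reciprocal of the standard deviation of crust edge lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .head_model import ReferenceSet, TriangleSurface
from .reconstruct import CrustMesh, SamplePointCloud, crust_reconstruct
from .virtual_1020 import CandidateGrid, LandmarkSet

__all__ = [
    "SamplingRule",
    "PerturbationRule",
    "SamplingReport",
    "uniform_sample",
    "cap_perturb",
    "uniformness_index",
    "ui_from_edge_lengths",
]


@dataclass(frozen=True)
class SamplingRule:
    n: int
    seed: int = 0

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("sample size must be at least 10")


@dataclass(frozen=True)
class PerturbationRule:
    max_distance: float = 13.0
    seed: int = 0

    def __post_init__(self):
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")


@dataclass
class SamplingReport:
    cloud: SamplePointCloud
    subset_counts: dict[str, int]
    chosen_names: list[str]


def uniform_sample(grid: CandidateGrid, rule: SamplingRule) -> SamplePointCloud:
    cloud, _ = uniform_sample_report(grid, rule)
    return cloud


def uniform_sample_report(grid: CandidateGrid, rule: SamplingRule):
    """Draw ``rule.n`` distinct candidates, at least one per subset, subset
    counts within one of each other; deterministic given the seed."""
    subsets = grid.subsets
    k = len(subsets)
    if rule.n < k:
        raise ValueError(f"sample size {rule.n} < number of subsets {k}")
    if rule.n > len(grid):
        raise ValueError(f"sample size {rule.n} exceeds candidate count {len(grid)}")
    rng = np.random.default_rng(rule.seed)
    names = sorted(subsets)
    base, extra = divmod(rule.n, k)
    counts = {name: base for name in names}
    for name in rng.choice(names, size=extra, replace=False):
        counts[str(name)] += 1
    for name in names:
        if counts[name] > len(subsets[name]):
            raise ValueError(
                f"subset {name!r} has {len(subsets[name])} candidates, "
                f"cannot supply {counts[name]}"
            )
    chosen: list[int] = []
    for name in names:
        idx = subsets[name]
        pick = rng.choice(idx, size=counts[name], replace=False)
        chosen.extend(int(i) for i in pick)
    cloud = SamplePointCloud(points=grid.points[chosen], refs=grid.refs)
    report = SamplingReport(
        cloud=cloud,
        subset_counts=counts,
        chosen_names=[grid.names[i] for i in chosen],
    )
    return cloud, report


def cap_perturb(
    landmarks: LandmarkSet,
    S: TriangleSurface,
    rule: PerturbationRule,
    refs: ReferenceSet | None = None,
) -> SamplePointCloud:
    """EEG-cap sampling simulation: for each landmark pick one surface-mesh
    vertex uniformly at random within ``max_distance`` mm (the nearest
    vertex when the radius is zero).  Collisions between neighbouring
    landmarks are re-drawn so the cloud stays pairwise distinct."""
    rng = np.random.default_rng(rule.seed)
    tree = cKDTree(S.vertices)
    chosen: list[int] = []
    for name in sorted(landmarks):
        p = landmarks[name]
        if rule.max_distance == 0:
            _, idx = tree.query(p)
            cand = [int(idx)]
        else:
            cand = sorted(tree.query_ball_point(p, rule.max_distance))
            if not cand:
                raise RuntimeError(
                    f"no mesh vertex within {rule.max_distance} mm of {name}; "
                    "ground-truth mesh too coarse"
                )
        free = [i for i in cand if i not in chosen]
        if not free:
            raise RuntimeError(f"all candidate vertices near {name} already used")
        chosen.append(int(rng.choice(free)) if rule.max_distance > 0 else free[0])
    return SamplePointCloud(points=S.vertices[chosen], refs=refs)


def ui_from_edge_lengths(lengths) -> float:
    """UI = 1 / sample SD of crust edge lengths (+inf when all equal)."""
    lengths = np.asarray(lengths, dtype=float)
    if len(lengths) < 2:
        return float("inf")
    sd = float(np.std(lengths, ddof=1))
    return float("inf") if sd == 0 else 1.0 / sd


def uniformness_index(cloud: SamplePointCloud, crust: CrustMesh | None = None) -> float:
    """Uniformness index of a sample cloud (reconstructs the crust unless a
    precomputed one is supplied)."""
    if crust is None:
        crust = crust_reconstruct(cloud)
    return ui_from_edge_lengths(crust.edge_lengths())
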