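"""Clonal-expansion correction: the LOD/linear count-calibration model.

Pooled sequencing overestimates how many plaques carry a given mutation:
below a limit of detection (LOD) copy numbers cannot be resolved at all, and
above it the observed count inflates linearly.  Calibration mixtures with
known copy numbers are fit with a piecewise model -- flat ("collapse to one")
at or below the LOD, ordinary least squares observed ~ expected above it --
where the LOD itself is found by a 1000-evaluation decreasing-step search
for the lowest squared error.  Observed counts are then inverted through the
line, clonality = (total - independent)/total is computed per animal, and
the mutant frequency is scaled by (1 - clonality) to give the
clonality-corrected mutation frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .calling import SamplePool, round_half_up


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationPoint:
    expected_count: int
    observed_count: int

    def __post_init__(self) -> None:
        if self.expected_count < 0 or self.observed_count < 0:
            raise ValueError("calibration counts must be non-negative")


@dataclass(frozen=True)
class ClonalityModel:
    """Piecewise calibration: counts <= lod collapse to 1; above, (obs - b)/m."""

    lod: int
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.lod < 0:
            raise ValueError("lod must be >= 0")
        if self.slope <= 0:
            raise ValueError("slope must be positive")


#: Parameters measured on the assay's own calibration mixtures; used when no
#: calibration data are supplied to a run.
DEFAULT_MODEL = ClonalityModel(lod=4, slope=1.1363, intercept=0.3123)


def _objective(points: Sequence[CalibrationPoint], lod: float):
    """Total squared error of the piecewise model at a candidate LOD.

    Points with observed > lod are fit by OLS observed ~ expected; points at
    or below collapse to a predicted copy number of 1 and are scored against
    their known expected count.
    """
    above = [p for p in points if p.observed_count > lod]
    below = [p for p in points if p.observed_count <= lod]
    if len(above) < 2 or len({p.expected_count for p in above}) < 2:
        return math.inf, None, None
    x = np.array([p.expected_count for p in above], dtype=float)
    y = np.array([p.observed_count for p in above], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        return math.inf, None, None
    sse = float(np.sum((y - (slope * x + intercept)) ** 2))
    sse += float(sum((p.expected_count - 1) ** 2 for p in below))
    return sse, float(slope), float(intercept)


def fit_lod_linear(points: Sequence[CalibrationPoint], n_evaluations: int = 1000) -> ClonalityModel:
    """Decreasing-step search for the LOD with the lowest squared error.

    The candidate range is [0, max expected]; a coarse grid is refined by
    repeatedly halving the step around the current best candidate until the
    evaluation budget is spent.  The LOD is reported as the integer count it
    implies (observed counts at or below it collapse to one).
    """
    points = list(points)
    if len(points) < 4:
        raise FitError("need at least 4 calibration points")
    max_expected = max(p.expected_count for p in points)
    if max_expected == 0:
        raise FitError("all calibration points have expected count 0")

    evaluations = 0
    cache: dict[float, tuple] = {}

    def evaluate(lod: float):
        nonlocal evaluations
        key = round(lod, 9)
        if key not in cache:
            cache[key] = _objective(points, lod)
            evaluations += 1
        return cache[key]

    step = max_expected / 2.0
    best_lod, best = None, (math.inf, None, None)
    # initial coarse grid
    for lod in np.arange(0.0, max_expected + 1e-9, step):
        result = evaluate(float(lod))
        if result[0] < best[0]:
            best_lod, best = float(lod), result
    if best_lod is None or not math.isfinite(best[0]):
        # fall back to a unit grid before giving up
        for lod in range(0, max_expected + 1):
            result = evaluate(float(lod))
            if result[0] < best[0]:
                best_lod, best = float(lod), result
    if best_lod is None or not math.isfinite(best[0]):
        raise FitError("degenerate calibration: no candidate LOD leaves >=2 points above it")

    while evaluations < n_evaluations and step > 1e-6:
        step /= 2.0
        for lod in (best_lod - step, best_lod + step):
            if not 0.0 <= lod <= max_expected:
                continue
            result = evaluate(lod)
            if result[0] < best[0]:
                best_lod, best = lod, result
            if evaluations >= n_evaluations:
                break

    _, slope, intercept = best
    return ClonalityModel(lod=int(round(best_lod)), slope=slope, intercept=intercept)


def lack_of_fit(points: Sequence[CalibrationPoint], model: ClonalityModel) -> float | None:
    """Pure-error F-test p-value for linearity of the above-LOD points.

    Needs replicated expected counts above the LOD; returns None when the
    decomposition is not possible.  Informational only.
    """
    above = [p for p in points if p.observed_count > model.lod]
    groups: dict[int, list[int]] = {}
    for p in above:
        groups.setdefault(p.expected_count, []).append(p.observed_count)
    n = len(above)
    m = len(groups)
    df_pe = n - m
    df_lof = m - 2
    if df_pe <= 0 or df_lof <= 0:
        return None
    sse_pe = sum(sum((y - np.mean(ys)) ** 2 for y in ys) for ys in groups.values())
    x = np.array([p.expected_count for p in above], dtype=float)
    y = np.array([p.observed_count for p in above], dtype=float)
    resid = y - (model.slope * x + model.intercept)
    sse = float(np.sum(resid**2))
    sse_lof = max(sse - sse_pe, 0.0)
    if sse_pe == 0:
        return None
    f = (sse_lof / df_lof) / (sse_pe / df_pe)
    return float(stats.f.sf(f, df_lof, df_pe))


def adjust_count(observed: int, model: ClonalityModel = DEFAULT_MODEL) -> int:
    """Invert an observed copy count through the LOD/linear model."""
    if observed < 1:
        raise ValueError("observed count must be >= 1")
    if observed <= model.lod:
        return 1
    return max(1, round_half_up((observed - model.intercept) / model.slope))


def clonality(total: int, independent: int) -> float:
    """(total - independent)/total within a sample or group; 0 when total is 0."""
    if not total >= independent >= 0:
        raise ValueError("need total >= independent >= 0")
    if total == 0:
        return 0.0
    return (total - independent) / total


def corrected_mutation_frequency(pool: SamplePool, clonality_fraction: float) -> float:
    """Mutant frequency scaled down by the clonal fraction: MF x (1 - clonality)."""
    if not 0.0 <= clonality_fraction <= 1.0:
        raise ValueError("clonality must be in [0, 1]")
    if pool.total_pfu <= 0:
        raise ValueError("total_pfu must be positive")
    return pool.mutant_frequency * (1.0 - clonality_fraction)


def fold_induction(treated_frequencies: Iterable[float], control_frequencies: Iterable[float]) -> float:
    """Ratio of group-mean corrected mutation frequencies, treated/control."""
    treated = float(np.mean(list(treated_frequencies)))
    control = float(np.mean(list(control_frequencies)))
    if control <= 0:
        raise ValueError("control group mean frequency must be positive")
    return treated / control


def read_calibration_tsv(path) -> list[CalibrationPoint]:
    points: list[CalibrationPoint] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("expected"):
                continue
            expected, observed = line.split("\t")[:2]
            points.append(CalibrationPoint(int(expected), int(observed)))
    return points


def write_calibration_tsv(points: Iterable[CalibrationPoint], path) -> None:
    with open(path, "w") as handle:
        handle.write("expected\tobserved\n")
        for p in points:
            handle.write(f"{p.expected_count}\t{p.observed_count}\n")
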