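"""Mutual information between reaction coordinates.

Couplings between the quaternary coordinate and the per-subunit tertiary
coordinates are measured with the Shannon mutual information

    I(X, Y) = sum_{x,y} P(x, y) ln[ P(x, y) / (P_X(x) P_Y(y)) ]

estimated from 2-D histograms of the paired samples.  The plug-in
estimate is biased upward for finite n, so the reported value is obtained
by computing the MI on random subsamples of decreasing size, fitting MI
against k = 1/n, and extrapolating to k = 0 (infinite data).  All values
are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .subspace import ProjectionSeries

__all__ = [
    "PairedSeries",
    "BinningSpec",
    "MIEstimate",
    "histogram_mi",
    "extrapolated_mi",
    "fit_mi_extrapolation",
    "mi_matrix",
    "truncate_at_closest_approach",
]


@dataclass
class PairedSeries:
    """Equal-length paired samples of two coordinates."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise ValueError("x and y lengths differ")
        if len(self.x) < 4:
            raise ValueError("need at least 4 paired samples")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class BinningSpec:
    """Histogram discretization defining P(x, y) and the marginals.

    By default each axis uses 10 equal-width bins spanning the data
    min-max; a fixed range can be supplied instead.
    """

    bins_x: int = 10
    bins_y: int = 10
    range_x: tuple[float, float] | None = None
    range_y: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.bins_x < 2 or self.bins_y < 2:
            raise ValueError("need at least 2 bins per axis")


@dataclass
class MIEstimate:
    """Extrapolated mutual information with its supporting fit.

    ``raw_values[i]`` is the mean plug-in MI over the replicates at
    ``subsample_sizes[i]``; ``k_values`` are the inverse sizes, and
    ``value`` is the intercept of the linear fit MI(k) at k = 0.
    """

    value: float  # nats
    raw_values: np.ndarray
    subsample_sizes: np.ndarray
    k_values: np.ndarray
    slope: float
    intercept: float
    per_trajectory: list[float] = field(default_factory=list)


def _axis_range(values: np.ndarray,
                given: tuple[float, float] | None) -> tuple[float, float]:
    lo, hi = given if given is not None else (float(values.min()),
                                              float(values.max()))
    if hi <= lo:  # constant coordinate: widen to a single occupied bin
        lo, hi = lo - 0.5, hi + 0.5
    return lo, hi


def histogram_mi(data: PairedSeries, spec: BinningSpec | None = None
                 ) -> float:
    """Plug-in histogram estimate of I(X, Y) in nats (non-negative).

    A constant x or y occupies a single bin and yields exactly zero, which
    is the correct answer rather than an error.
    """
    spec = spec or BinningSpec()
    counts, _, _ = np.histogram2d(
        data.x, data.y, bins=(spec.bins_x, spec.bins_y),
        range=(_axis_range(data.x, spec.range_x),
               _axis_range(data.y, spec.range_y)))
    p = counts / counts.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    occupied = p > 0
    ratio = p[occupied] / np.outer(px, py)[occupied]
    mi = float(np.sum(p[occupied] * np.log(ratio)))
    return max(mi, 0.0)


def extrapolated_mi(data: PairedSeries,
                    spec: BinningSpec | None = None,
                    subsample_fractions: Sequence[float] = (1.0, 0.5, 0.25, 0.125),
                    replicates: int = 10,
                    seed: int = 0) -> MIEstimate:
    """Finite-sample-corrected MI: extrapolate subsampled MI to k = 0.

    The plug-in MI is computed at each subsample size (averaging
    ``replicates`` random subsamples drawn without replacement; histogram
    ranges are fixed from the full data so only sampling density varies),
    and a least-squares line MI = a k + b with k = 1/n is extrapolated to
    the infinite-data point k = 0.  Deterministic given ``seed``.
    """
    spec = spec or BinningSpec()
    full_spec = BinningSpec(
        bins_x=spec.bins_x, bins_y=spec.bins_y,
        range_x=_axis_range(data.x, spec.range_x),
        range_y=_axis_range(data.y, spec.range_y))
    fractions = sorted(set(float(f) for f in subsample_fractions),
                       reverse=True)
    if not fractions or fractions[0] > 1.0 or fractions[-1] <= 0.0:
        raise ValueError("subsample fractions must lie in (0, 1]")
    sizes = np.array([int(round(f * data.n)) for f in fractions])
    min_needed = 10 * max(spec.bins_x, spec.bins_y)
    if sizes.min() < min_needed:
        raise ValueError(
            f"smallest subsample ({sizes.min()}) below the minimum of "
            f"{min_needed} (10 x max bin count); provide more samples or "
            f"larger fractions")
    rng = np.random.default_rng(seed)
    raw = np.empty(len(sizes))
    for i, size in enumerate(sizes):
        if size == data.n:
            raw[i] = histogram_mi(data, full_spec)
            continue
        vals = []
        for _ in range(replicates):
            pick = rng.choice(data.n, size=size, replace=False)
            vals.append(histogram_mi(
                PairedSeries(data.x[pick], data.y[pick]), full_spec))
        raw[i] = float(np.mean(vals))
    k = 1.0 / sizes
    slope, intercept = fit_mi_extrapolation(sizes, raw)
    return MIEstimate(value=intercept, raw_values=raw,
                      subsample_sizes=sizes, k_values=k,
                      slope=slope, intercept=intercept)


def fit_mi_extrapolation(sizes: Sequence[int],
                         mi_values: Sequence[float]
                         ) -> tuple[float, float]:
    """Least-squares line through the (k = 1/n, MI) points.

    Returns ``(slope, intercept)``; the intercept is the finite-sample
    corrected MI at k = 0.
    """
    k = 1.0 / np.asarray(sizes, dtype=float)
    slope, intercept = np.polyfit(k, np.asarray(mi_values, dtype=float), 1)
    return float(slope), float(intercept)


def _as_paired(sx: ProjectionSeries, sy: ProjectionSeries) -> PairedSeries:
    if not np.array_equal(sx.frame_times, sy.frame_times):
        raise ValueError(
            f"frame times of {sx.coordinate_id!r} and {sy.coordinate_id!r} "
            f"differ")
    return PairedSeries(sx.values, sy.values)


def mi_matrix(coords: Mapping[str, ProjectionSeries]
              | Sequence[Mapping[str, ProjectionSeries]],
              pairs: Sequence[tuple[str, str]],
              spec: BinningSpec | None = None,
              subsample_fractions: Sequence[float] = (1.0, 0.5, 0.25, 0.125),
              replicates: int = 10,
              seed: int = 0) -> dict[tuple[str, str], MIEstimate]:
    """Extrapolated MI for each requested coordinate pair.

    ``coords`` may be a single mapping coordinate_id -> series, or a
    sequence of such mappings (one per trajectory); in the latter case the
    per-trajectory extrapolated values are averaged, mirroring the
    averaging of the MI over independent transitions.
    """
    if isinstance(coords, Mapping):
        trajectories = [coords]
    else:
        trajectories = list(coords)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(len(pairs) * len(trajectories))
    out: dict[tuple[str, str], MIEstimate] = {}
    for p, (id_x, id_y) in enumerate(pairs):
        estimates = []
        for t, traj in enumerate(trajectories):
            data = _as_paired(traj[id_x], traj[id_y])
            estimates.append(extrapolated_mi(
                data, spec, subsample_fractions, replicates,
                seed=int(child_seeds[p * len(trajectories) + t] % (2**31))))
        first = estimates[0]
        out[(id_x, id_y)] = MIEstimate(
            value=float(np.mean([e.value for e in estimates])),
            raw_values=first.raw_values,
            subsample_sizes=first.subsample_sizes,
            k_values=first.k_values,
            slope=first.slope,
            intercept=first.intercept,
            per_trajectory=[e.value for e in estimates],
        )
    return out


def truncate_at_closest_approach(series: ProjectionSeries,
                                 rotrmsd_series: ProjectionSeries
                                 ) -> ProjectionSeries:
    """Drop frames after the closest approach to the target state.

    Frames after the global minimum of the rotRMSD-to-reference series are
    discarded (the minimum frame itself is kept); ties are broken by the
    earliest minimum.  Transitions are analyzed only up to their closest
    approach so that post-transition fluctuations do not dominate the MI.
    """
    if not np.array_equal(series.frame_times, rotrmsd_series.frame_times):
        raise ValueError("series and rotRMSD series times differ")
    cut = int(np.argmin(rotrmsd_series.values)) + 1
    return series.truncated(cut)
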