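"""Per-pigment statistics extracted from trajectories.

This module turns a trajectory of LYS+RET coordinates into the quantities
the regression consumes: per-frame angle time series, their per-pigment
medians, per-atom root-mean-square fluctuations (RMSF) and the area under
the RMSF profile, and frequency distributions used to compare paralog
groups (blue-shifted Sws2a vs violet-shifted Sws2b).

Torsion medians are computed circularly: each series is re-centred on its
circular mean, the ordinary median is taken on the re-centred values, and
the result is mapped back to (−180°, 180°].  For a unimodal series away
from the ±180° seam this reproduces the plain median; for a series
straddling the seam it avoids the gross artefact of averaging +179° and
−179° to ~0°.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import MissingAtomError, RetinotuneError
from .geometry import AngleRegistry, evaluate_registry

if TYPE_CHECKING:  # pragma: no cover
    from .io import Trajectory

__all__ = [
    "FeatureSeries",
    "FeatureSummary",
    "Histogram",
    "ParalogComparison",
    "angle_time_series",
    "summarize",
    "circular_median",
    "rmsf",
    "auc_rmsf",
    "frequency_distribution",
    "compare_paralog_distributions",
]


def wrap_degrees(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to the torsion branch (−180, 180]."""
    w = -(np.mod(-np.asarray(x, dtype=float) + 180.0, 360.0) - 180.0)
    return float(w) if np.isscalar(x) else w


@dataclass
class FeatureSeries:
    """Per-frame values of each registered parameter for one pigment."""

    pigment_id: str
    values: dict[str, np.ndarray]
    kinds: dict[str, str]  # name -> "torsion" | "geometric"

    def __post_init__(self) -> None:
        lengths = {name: len(v) for name, v in self.values.items()}
        if lengths and len(set(lengths.values())) != 1:
            raise RetinotuneError(f"unequal series lengths: {lengths}")
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.values.values()))) if self.values else 0

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values)
        df.insert(0, "frame", np.arange(self.n_frames))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, pigment_id: str, kinds: Mapping[str, str]
    ) -> "FeatureSeries":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c != "frame"]
        return cls(pigment_id, {c: df[c].to_numpy(float) for c in cols}, dict(kinds))


@dataclass
class FeatureSummary:
    """Per-pigment summary consumed by the regression stage."""

    medians: dict[str, float]
    frame_count: int
    auc_rmsf: float | None = None


def angle_time_series(traj: "Trajectory", registry: AngleRegistry) -> FeatureSeries:
    """Evaluate every registry definition on every frame.

    Geometry errors are re-raised annotated with the offending frame index.
    """
    series: dict[str, list[float]] = {d.name: [] for d in registry}
    for t in range(traj.n_frames):
        frame = traj.frame_mapping(t)
        try:
            vals = evaluate_registry(frame, registry)
        except (MissingAtomError, RetinotuneError) as exc:
            raise type(exc)(f"frame {t}: {exc}") from exc
        for name, v in vals.items():
            series[name].append(v)
    kinds = {d.name: d.kind for d in registry}
    return FeatureSeries(
        traj.pigment_id or "trajectory",
        {k: np.asarray(v) for k, v in series.items()},
        kinds,
    )


def circular_mean(values_deg: Sequence[float]) -> float:
    th = np.radians(np.asarray(values_deg, dtype=float))
    s, c = np.sin(th).mean(), np.cos(th).mean()
    if np.hypot(s, c) < 1e-12:
        # perfectly balanced (e.g. antipodal pair): no meaningful centre
        return 0.0
    return float(np.degrees(np.arctan2(s, c)))


def circular_median(values_deg: Sequence[float]) -> float:
    """Median of a torsion series, robust to the ±180° branch seam."""
    v = np.asarray(values_deg, dtype=float)
    if v.size == 0:
        raise RetinotuneError("empty series has no median")
    mu = circular_mean(v)
    dev = wrap_degrees(v - mu)
    return float(wrap_degrees(mu + np.median(dev)))


def summarize(series: FeatureSeries, auc: float | None = None) -> FeatureSummary:
    """Per-parameter medians (circular for torsions) plus the frame count."""
    if series.n_frames == 0:
        raise RetinotuneError("cannot summarize an empty FeatureSeries")
    medians: dict[str, float] = {}
    for name, vals in series.values.items():
        if series.kinds.get(name, "geometric") == "torsion":
            medians[name] = circular_median(vals)
        else:
            medians[name] = float(np.median(vals))
    return FeatureSummary(medians=medians, frame_count=series.n_frames, auc_rmsf=auc)


def _kabsch_align(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares superposition of ``mobile`` (n,3) onto ``ref`` (n,3)."""
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ r + ref.mean(axis=0)


def rmsf(
    traj: "Trajectory",
    atom_subset: Sequence[str] | None = None,
    align: bool = True,
) -> pd.Series:
    """Per-atom root-mean-square fluctuation about the mean position (Å).

    RMSF_i = sqrt( (1/T) Σ_t ‖v_{i,t} − v̄_i‖² ).  With ``align=True``
    (default, matching standard MD practice) every frame is first
    least-squares superposed on the mean structure of the selected atoms;
    the mean is refined once after an initial alignment to frame 0.
    """
    names = list(atom_subset) if atom_subset is not None else list(traj.atom_names)
    missing = [a for a in names if a not in traj.atom_names]
    if missing:
        raise MissingAtomError(f"atoms absent from trajectory: {missing}")
    if traj.n_frames < 2:
        raise RetinotuneError("RMSF requires at least 2 frames")
    idx = [traj.atom_names.index(a) for a in names]
    x = traj.coords[:, idx, :].astype(float)
    if align:
        aligned = np.stack([_kabsch_align(f, x[0]) for f in x])
        ref = aligned.mean(axis=0)
        x = np.stack([_kabsch_align(f, ref) for f in x])
    mean = x.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
    return pd.Series(fluct, index=names, name="rmsf")


def auc_rmsf(per_atom: Sequence[float] | pd.Series) -> float:
    """Trapezoidal area under the RMSF profile over atom index (unit spacing)."""
    v = np.asarray(per_atom, dtype=float)
    if v.size < 2:
        raise RetinotuneError("AUC needs at least 2 atoms")
    return float(np.trapezoid(v))


@dataclass
class Histogram:
    """Normalized frequency distribution: masses sum to 1."""

    edges: np.ndarray
    masses: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def frequency_distribution(
    values: Sequence[float], bin_width: float = 2.0
) -> Histogram:
    """Histogram with bins of ``bin_width`` degrees aligned to multiples of it."""
    if bin_width <= 0:
        raise RetinotuneError("bin_width must be positive")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise RetinotuneError("cannot histogram an empty series")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    return Histogram(edges=edges, masses=counts / counts.sum())


@dataclass
class ParalogComparison:
    """Per-paralog-group distribution statistics for one parameter."""

    parameter: str
    histograms: dict[str, Histogram]
    iqr: dict[str, float]
    variance: dict[str, float]

    def wider_group(self) -> str:
        return max(self.iqr, key=self.iqr.get)


def compare_paralog_distributions(
    series_by_pigment: Mapping[str, FeatureSeries],
    paralog_of: Mapping[str, str],
    parameter: str,
    bin_width: float = 2.0,
) -> ParalogComparison:
    """Pool per-frame values of ``parameter`` by paralog group and compare spread.

    Torsion values are re-centred on each pigment's circular mean before
    pooling so that spread statistics measure fluctuation width rather than
    between-pigment offsets (and are immune to the ±180° seam).
    """
    pooled: dict[str, list[np.ndarray]] = {}
    kind = None
    for pid, series in series_by_pigment.items():
        if parameter not in series.values:
            raise RetinotuneError(f"{pid}: parameter {parameter!r} not in series")
        kind = series.kinds.get(parameter, "geometric")
        v = series.values[parameter]
        if kind == "torsion":
            v = wrap_degrees(v - circular_mean(v))
        else:
            v = v - np.median(v)
        pooled.setdefault(paralog_of[pid], []).append(np.asarray(v))
    hists, iqr, var = {}, {}, {}
    for group, chunks in pooled.items():
        allv = np.concatenate(chunks)
        hists[group] = frequency_distribution(allv, bin_width=bin_width)
        q75, q25 = np.percentile(allv, [75, 25])
        iqr[group] = float(q75 - q25)
        var[group] = float(np.var(allv))
    return ParalogComparison(parameter, hists, iqr, var)
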