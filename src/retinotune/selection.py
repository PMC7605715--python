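"""Sparse linear-model selection for λ_max prediction.

The modelling table is small — 11 pigments × 19 parameter medians — so the
procedure is deliberately simple and exhaustive:

1. *Correlation screen*: rank each parameter by the squared Pearson
   correlation (r²) of its median with experimental λ_max; keep the top
   seven after applying a declarative exclusion list (parameters judged
   non-linear on inspection are excluded as data, not re-derived).
2. *Exhaustive subset search*: fit ordinary least squares for every
   non-empty subset of the shortlist (2^k − 1 models) and rank by BIC,
   using the leaps/regsubsets convention

       BIC = n·ln(RSS/n) + (k+1)·ln(n)

   with additive constants dropped (rank-equivalent to the full Gaussian
   likelihood form).  Ties break toward fewer terms, then lexicographic
   term order.
3. *+ΔBIC window*: all models within ``bic_window`` of the best BIC are
   reported; with only ~10 observations, several near-equivalent models
   usually survive, and a fewest-terms tie-break picks one when a single
   model is required.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ModelFitError, RetinotuneError
from .io import PigmentDataset

__all__ = [
    "LinearModel",
    "ScreenResult",
    "SubsetSearchResult",
    "DEFAULT_SHORTLIST",
    "default_screen_exclusions",
    "bic_score",
    "correlation_screen",
    "fit_ols",
    "exhaustive_subset_search",
]

_RSS_FLOOR = 1e-12  # keeps ln(RSS/n) finite on (numerically) perfect fits

#: The seven-parameter shortlist used by the published selection procedure.
DEFAULT_SHORTLIST: tuple[str, ...] = (
    "Torsion 3",
    "Torsion 9",
    "Torsion 10",
    "Torsion 11",
    "Torsion 12",
    "Angle 1",
    "Angle 3",
)


def default_screen_exclusions() -> tuple[str, ...]:
    """Parameters excluded from the screen by default.

    The original shortlist was cut after a visual-inspection step that
    rejected parameters without a genuinely linear relationship; that
    judgement is encoded declaratively as the complement of
    :data:`DEFAULT_SHORTLIST` so the pipeline stays deterministic.
    """
    from .geometry import default_registry

    return tuple(n for n in default_registry().names if n not in DEFAULT_SHORTLIST)


@dataclass(frozen=True)
class LinearModel:
    """A fitted (or published) linear model: λ_max = intercept + Σ coef·median."""

    terms: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]
    n: int | None = None
    rss: float | None = None
    r_squared: float | None = None
    bic: float | None = None
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.coefficients):
            raise RetinotuneError("terms and coefficients length mismatch")

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coefficients))

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "intercept": self.intercept,
            "coefficients": list(self.coefficients),
            "n": self.n,
            "rss": self.rss,
            "r_squared": self.r_squared,
            "bic": self.bic,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            terms=tuple(d["terms"]),
            intercept=float(d["intercept"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            n=d.get("n"),
            rss=d.get("rss"),
            r_squared=d.get("r_squared"),
            bic=d.get("bic"),
            provenance=d.get("provenance", "fitted"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ScreenResult:
    """Outcome of the univariate correlation screen."""

    r2: dict[str, float]
    ranked: list[str]
    shortlist: list[str]
    excluded: list[str]
    dropped_constant: list[str] = field(default_factory=list)


def bic_score(n: int, rss: float, k: int) -> float:
    """leaps/regsubsets-style BIC for a k-term model with intercept."""
    return n * float(np.log(max(rss, _RSS_FLOOR) / n)) + (k + 1) * float(np.log(n))


def _design(dataset: PigmentDataset, terms: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    med = dataset.medians_frame()
    missing = [t for t in terms if t not in med.columns]
    if missing:
        raise ModelFitError(f"terms absent from median table: {missing}")
    x = med[list(terms)].to_numpy(float)
    y = dataset.lambda_max()
    return x, y


def correlation_screen(
    dataset: PigmentDataset,
    exclude: Iterable[str] = (),
    shortlist_size: int = 7,
) -> ScreenResult:
    """Rank parameters by squared Pearson correlation with λ_max.

    Constant (zero-variance) parameters have undefined r² and are dropped
    with a warning.  ``exclude`` removes names before the shortlist is cut.
    """
    if len(dataset) < 3:
        raise ModelFitError("correlation screen needs at least 3 pigments")
    med = dataset.medians_frame()
    y = dataset.lambda_max()
    excl = list(exclude)
    r2: dict[str, float] = {}
    dropped: list[str] = []
    for name in med.columns:
        x = med[name].to_numpy(float)
        if np.std(x) < 1e-12:
            dropped.append(name)
            warnings.warn(
                f"parameter {name!r} is constant across pigments; r² undefined, dropped",
                stacklevel=2,
            )
            continue
        r = np.corrcoef(x, y)[0, 1]
        r2[name] = float(r * r)
    ranked = sorted(r2, key=lambda nm: (-r2[nm], nm))
    shortlist = [nm for nm in ranked if nm not in excl][:shortlist_size]
    return ScreenResult(
        r2=r2, ranked=ranked, shortlist=shortlist, excluded=excl, dropped_constant=dropped
    )


def fit_ols(dataset: PigmentDataset, terms: Sequence[str]) -> LinearModel:
    """Ordinary least squares of λ_max on the given parameter medians."""
    terms = tuple(terms)
    x, y = _design(dataset, terms)
    n, k = x.shape
    if n <= k + 1:
        raise ModelFitError(
            f"need n > k+1 observations for {k} terms; have n={n}"
        )
    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        # name the collinear offenders: columns whose removal restores full rank
        collinear = [
            t
            for i, t in enumerate(terms)
            if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1)) == rank
        ]
        raise ModelFitError(f"rank-deficient design; collinear terms: {collinear}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return LinearModel(
        terms=terms,
        intercept=float(beta[0]),
        coefficients=tuple(float(b) for b in beta[1:]),
        n=n,
        rss=rss,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        bic=bic_score(n, rss, k),
    )


@dataclass
class SubsetSearchResult:
    """All subset models ranked by BIC, plus the +Δ window."""

    models: list[LinearModel]
    best: LinearModel
    window: list[LinearModel]
    window_delta: float

    def select_parsimonious(self) -> LinearModel:
        """Within the window, prefer fewest terms, then lowest BIC."""
        return min(self.window, key=lambda m: (len(m.terms), m.bic, m.terms))


def exhaustive_subset_search(
    dataset: PigmentDataset,
    shortlist: Sequence[str],
    bic_window: float = 2.0,
) -> SubsetSearchResult:
    """Fit every non-empty subset of ``shortlist`` and rank by BIC.

    Subsets whose design would be saturated (n ≤ k+1) or rank-deficient are
    skipped; at least one subset must be fittable.
    """
    shortlist = list(shortlist)
    if not shortlist:
        raise ModelFitError("empty shortlist")
    if len(shortlist) > 12:
        raise ModelFitError("shortlist too large for exhaustive enumeration (>12)")
    models: list[LinearModel] = []
    for k in range(1, len(shortlist) + 1):
        for subset in combinations(shortlist, k):
            try:
                models.append(fit_ols(dataset, subset))
            except ModelFitError:
                continue
    if not models:
        raise ModelFitError("no fittable subset (too few observations?)")
    models.sort(key=lambda m: (m.bic, len(m.terms), m.terms))
    best = models[0]
    window = [m for m in models if m.bic <= best.bic + bic_window]
    return SubsetSearchResult(models=models, best=best, window=window, window_delta=bic_window)
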