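"""Prediction and cross-validation of λ_max models.

Two distinct leave-one-out schemes are implemented and must not be
conflated:

* **leave-one-pigment-out** — the model's *terms are fixed*; only the
  coefficients are re-estimated on the remaining n−1 pigments before the
  held-out pigment is predicted.
* **leave-one-species-out** — both paralogs of a two-paralog species are
  removed and the *entire selection procedure* (correlation screen →
  exhaustive BIC search → +2-BIC window with a fewest-terms tie-break) is
  re-run on the remaining nine pigments before the pair is predicted.

A registry of the five published models is bundled: the full three-term
model and the four species-excluded models, with coefficients exactly as
printed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ModelFitError, RetinotuneError
from .features import FeatureSummary
from .io import PigmentDataset
from .selection import (
    LinearModel,
    correlation_screen,
    exhaustive_subset_search,
    fit_ols,
)

__all__ = [
    "predict",
    "published_models",
    "PublishedModelRegistry",
    "ValidationReport",
    "error_metrics",
    "loo_by_pigment",
    "loo_by_species",
]


def predict(
    model: LinearModel,
    summary: FeatureSummary | Mapping[str, float],
    observed_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """λ_max (nm) = intercept + Σ coefficient × median.

    ``summary`` may be a :class:`FeatureSummary` or a plain name→median
    mapping.  If ``observed_ranges`` is given, a warning is emitted for any
    median outside the range the model was trained on (extrapolation is the
    documented failure mode of the zebrafish-like outlier).
    """
    medians = summary.medians if isinstance(summary, FeatureSummary) else dict(summary)
    missing = [t for t in model.terms if t not in medians]
    if missing:
        raise RetinotuneError(f"prediction is missing model terms: {missing}")
    if observed_ranges is not None:
        for t in model.terms:
            rng = observed_ranges.get(t)
            if rng is not None and not (rng[0] <= medians[t] <= rng[1]):
                warnings.warn(
                    f"median {t!r}={medians[t]:.3f}° outside training range "
                    f"[{rng[0]:.3f}, {rng[1]:.3f}]°; prediction extrapolates",
                    stacklevel=2,
                )
    value = model.intercept + sum(
        c * medians[t] for t, c in zip(model.terms, model.coefficients)
    )
    if not np.isfinite(value):
        raise RetinotuneError("non-finite prediction")
    return float(value)


# ---------------------------------------------------------------------------
# published models

_PUBLISHED: dict[str, dict] = {
    # full three-term model over all 11 pigments
    "eq1": {
        "terms": ("Angle 3", "Torsion 3", "Torsion 12"),
        "intercept": 2677.5348,
        "coefficients": (-17.052, 5.1634, 2.3642),
        "excluded_species": None,
    },
    "eq2": {
        "terms": ("Torsion 12", "Angle 3"),
        "intercept": 2761.5524,
        "coefficients": (2.405, -17.64),
        "excluded_species": "medaka",
    },
    "eq3": {
        "terms": ("Torsion 10", "Angle 1", "Angle 3"),
        "intercept": 4201.6725,
        "coefficients": (-1.4975, -24.7764, -3.2922),
        "excluded_species": "spotted flounder",
    },
    "eq4": {
        "terms": ("Torsion 10", "Angle 3"),
        "intercept": 2706.2512,
        "coefficients": (-3.1214, -13.8215),
        "excluded_species": "bluefin killifish",
    },
    "eq5": {
        "terms": ("Torsion 9", "Torsion 10", "Torsion 11", "Torsion 12", "Angle 3"),
        "intercept": 5624.1521,
        "coefficients": (3.6078, -1.8923, -11.0413, 16.0527, -20.9014),
        "excluded_species": "guppy",
    },
}


@dataclass
class PublishedModelRegistry:
    """The five published λ_max models, coefficients as printed."""

    models: dict[str, LinearModel]
    excluded_species: dict[str, str | None]

    def get(self, key: str) -> LinearModel:
        if key not in self.models:
            raise KeyError(f"unknown model {key!r}; have {sorted(self.models)}")
        return self.models[key]

    def to_json(self, path: str | Path) -> None:
        doc = {
            key: {**m.to_dict(), "excluded_species": self.excluded_species[key]}
            for key, m in self.models.items()
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PublishedModelRegistry":
        doc = json.loads(Path(path).read_text())
        models = {k: LinearModel.from_dict(v) for k, v in doc.items()}
        excluded = {k: v.get("excluded_species") for k, v in doc.items()}
        return cls(models=models, excluded_species=excluded)


def published_models() -> PublishedModelRegistry:
    models = {
        key: LinearModel(
            terms=spec["terms"],
            intercept=spec["intercept"],
            coefficients=spec["coefficients"],
            provenance="published",
        )
        for key, spec in _PUBLISHED.items()
    }
    excluded = {key: spec["excluded_species"] for key, spec in _PUBLISHED.items()}
    return PublishedModelRegistry(models=models, excluded_species=excluded)


# ---------------------------------------------------------------------------
# validation reports


@dataclass
class ValidationReport:
    """Per-pigment out-of-sample (or in-sample) predictions and errors."""

    scheme: str  # "full" | "loo-pigment" | "loo-species"
    pigment_ids: list[str]
    predicted: np.ndarray
    experimental: np.ndarray
    metrics: dict[str, float] = field(default_factory=dict)
    selected_model: LinearModel | None = None
    flagged_folds: list[str] = field(default_factory=list)
    extra_metrics: dict[str, float] = field(default_factory=dict)

    @property
    def abs_errors(self) -> np.ndarray:
        return np.abs(self.predicted - self.experimental)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "pigments": self.pigment_ids,
            "predicted_nm": [round(float(p), 2) for p in self.predicted],
            "experimental_nm": list(map(float, self.experimental)),
            "abs_error_nm": [round(float(e), 2) for e in self.abs_errors],
            "metrics": self.metrics,
            "extra_metrics": self.extra_metrics,
            "selected_model": (
                self.selected_model.to_dict() if self.selected_model else None
            ),
            "flagged_folds": self.flagged_folds,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def error_metrics(
    predicted: Sequence[float], experimental: Sequence[float]
) -> dict[str, float]:
    """R² (squared Pearson correlation) and absolute-error summary in nm."""
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if p.size < 2:
        raise RetinotuneError("error metrics need at least 2 predictions")
    ok = np.isfinite(p)
    errs = np.abs(p[ok] - e[ok])
    if p[ok].size >= 2 and np.std(p[ok]) > 0 and np.std(e[ok]) > 0:
        r = float(np.corrcoef(p[ok], e[ok])[0, 1])
        r2 = r * r
    else:
        r2 = float("nan")
    return {
        "r_squared": float(r2),
        "mean_abs_error_nm": float(errs.mean()),
        "min_abs_error_nm": float(errs.min()),
        "max_abs_error_nm": float(errs.max()),
    }


def full_model_report(dataset: PigmentDataset, terms: Sequence[str]) -> ValidationReport:
    """Fit on all pigments and report in-sample fitted values."""
    model = fit_ols(dataset, terms)
    preds = np.array([predict(model, r.feature_summary) for r in dataset])
    exp = dataset.lambda_max()
    return ValidationReport(
        scheme="full",
        pigment_ids=[r.pigment_id for r in dataset],
        predicted=preds,
        experimental=exp,
        metrics=error_metrics(preds, exp),
        selected_model=model,
    )


def loo_by_pigment(dataset: PigmentDataset, terms: Sequence[str]) -> ValidationReport:
    """Leave-one-pigment-out with *fixed* terms; coefficients re-weighted per fold."""
    n = len(dataset)
    if n < len(terms) + 3:
        raise ModelFitError(
            f"LOO needs n ≥ |terms|+3; have n={n} for {len(terms)} terms"
        )
    preds = np.full(n, np.nan)
    flagged: list[str] = []
    ids = [r.pigment_id for r in dataset]
    for i, record in enumerate(dataset):
        rest = dataset.drop_index(i)
        try:
            fold_model = fit_ols(rest, terms)
        except ModelFitError:
            flagged.append(ids[i])
            continue
        preds[i] = predict(fold_model, record.feature_summary)
    exp = dataset.lambda_max()
    report = ValidationReport(
        scheme="loo-pigment",
        pigment_ids=ids,
        predicted=preds,
        experimental=exp,
        flagged_folds=flagged,
    )
    report.metrics = error_metrics(preds, exp)
    return report


def loo_by_species(
    dataset: PigmentDataset,
    species: str,
    exclude: Iterable[str] = (),
    shortlist_size: int = 7,
    bic_window: float = 2.0,
) -> ValidationReport:
    """Remove both paralogs of ``species``, re-select a model, predict the pair.

    The report's R² is ambiguous for a 2-point hold-out, so three labelled
    variants are computed: over the 9 training pigments (in-sample), over
    the 2 held-out pigments (error summary only), and over all 11.
    """
    eligible = dataset.species_with_both_paralogs()
    if species not in eligible:
        raise RetinotuneError(
            f"species {species!r} does not have both Sws2a and Sws2b records; "
            f"eligible species: {sorted(eligible)}"
        )
    train = dataset.drop_species(species)
    held = [r for r in dataset.records if r.species == species]
    screen = correlation_screen(train, exclude=exclude, shortlist_size=shortlist_size)
    search = exhaustive_subset_search(train, screen.shortlist, bic_window=bic_window)
    model = search.select_parsimonious()
    held_pred = np.array([predict(model, r.feature_summary) for r in held])
    held_exp = np.array([r.lambda_max_exp for r in held])
    train_pred = np.array([predict(model, r.feature_summary) for r in train])
    train_exp = train.lambda_max()
    all_pred = np.concatenate([train_pred, held_pred])
    all_exp = np.concatenate([train_exp, held_exp])
    train_metrics = error_metrics(train_pred, train_exp)
    all_metrics = error_metrics(all_pred, all_exp)
    held_err = np.abs(held_pred - held_exp)
    report = ValidationReport(
        scheme="loo-species",
        pigment_ids=[r.pigment_id for r in held],
        predicted=held_pred,
        experimental=held_exp,
        selected_model=model,
        metrics={
            "mean_abs_error_nm": float(held_err.mean()),
            "min_abs_error_nm": float(held_err.min()),
            "max_abs_error_nm": float(held_err.max()),
        },
        extra_metrics={
            "r_squared_train": train_metrics["r_squared"],
            "r_squared_all": all_metrics["r_squared"],
            "r_squared_heldout": (
                float("nan") if len(held) < 3 else error_metrics(held_pred, held_exp)["r_squared"]
            ),
        },
    )
    return report
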