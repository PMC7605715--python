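"""Synthetic data with known ground truth.

No real MD output ships with the package; every stage is instead testable
against generators whose ground truth is known by construction:

* :func:`synth_median_table` — an 11-pigment modelling table whose λ_max
  values are produced by a known linear model of three parameter medians
  plus Gaussian noise.  The default layout mirrors the study scale (seven
  species, four of them with both Sws2a and Sws2b paralogs) and the default
  generating model is the published full model, so the selection and
  validation machinery runs under study-like conditions.
* :func:`synth_angle_series` — per-frame angle fluctuations around each
  pigment's parameter means: wrapped normal for torsions, truncated normal
  for geometric angles, with wider fluctuation widths for violet-shifted
  Sws2b pigments than for blue-shifted Sws2a (default 8° vs 2°), emulating
  the qualitative paralog difference seen in the trajectory distributions.
* :func:`synth_coordinates` / :func:`synth_trajectory` — inverse-geometry
  constructions: a 3- or 4-atom frame realising an exact target angle, and
  a jittered idealized LYS+RET structure exercising the full
  trajectory → series → summary path.
* :func:`parameter_recovery_experiment` — the screen → subset-search → fit
  pipeline run on replicated synthetic tables, reporting how often the true
  term set is recovered and the bias/RMSE of the coefficients.

All generators are seed-deterministic: the same spec and seed reproduce the
same output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .exceptions import RetinotuneError
from .features import FeatureSeries, FeatureSummary, wrap_degrees
from .geometry import (
    AngleDefinition,
    AngleRegistry,
    bond_angle,
    default_registry,
    dihedral,
)
from .io import PigmentDataset, PigmentRecord, Trajectory
from .selection import LinearModel, correlation_screen, exhaustive_subset_search, fit_ols
from .validation import published_models

__all__ = [
    "SyntheticSpec",
    "synth_median_table",
    "synth_angle_series",
    "synth_coordinates",
    "synth_trajectory",
    "idealized_frame",
    "parameter_recovery_experiment",
    "RecoveryResult",
    "DEFAULT_LAYOUT",
]

#: Study-scale layout: 11 pigments over 7 species, 4 species with both paralogs.
DEFAULT_LAYOUT: tuple[tuple[str, str], ...] = (
    ("spotted flounder", "Sws2a"),
    ("spotted flounder", "Sws2b"),
    ("slime flounder", "Sws2a"),
    ("olive flounder", "Sws2a"),
    ("guppy", "Sws2a"),
    ("guppy", "Sws2b"),
    ("medaka", "Sws2a"),
    ("medaka", "Sws2b"),
    ("bluefin killifish", "Sws2a"),
    ("bluefin killifish", "Sws2b"),
    ("zebrafish", "Sws2"),
)


def _default_mean_priors() -> dict[str, tuple[float, float]]:
    """(centre, between-pigment sd) in degrees for each parameter's mean.

    Centres follow the idealized moiety geometry (trans polyene backbone,
    11-cis kink, near-eclipsed methyl torsions); the three generating terms
    get spreads sized so the implied λ_max range spans roughly the violet-
    to-blue window the real pigments occupy.
    """
    return {
        "Torsion 1": (-170.0, 2.0),
        "Torsion 2": (-40.0, 3.0),
        "Torsion 3": (12.0, 2.0),
        "Torsion 4": (178.0, 2.0),
        "Torsion 5": (179.0, 2.0),
        "Torsion 6": (178.0, 2.0),
        "Torsion 7": (179.0, 2.0),
        "Torsion 8": (-8.0, 3.0),
        "Torsion 9": (178.0, 2.0),
        "Torsion 10": (179.0, 2.0),
        "Torsion 11": (178.0, 2.0),
        "Torsion 12": (-5.0, 3.0),
        "Torsion 13": (176.0, 3.0),
        "Torsion 14": (178.0, 3.0),
        "Torsion 15": (65.0, 4.0),
        "Angle 1": (125.0, 1.5),
        "Angle 2": (120.0, 1.5),
        "Angle 3": (134.5, 1.2),
        "Angle 4": (122.0, 1.5),
    }


@dataclass
class SyntheticSpec:
    """Everything needed to regenerate one synthetic dataset."""

    layout: tuple[tuple[str, str], ...] = DEFAULT_LAYOUT
    n_frames: int = 1000
    true_model: LinearModel = field(
        default_factory=lambda: published_models().get("eq1")
    )
    noise_sigma_nm: float = 6.8
    width_sws2a_deg: float = 2.0
    width_sws2b_deg: float = 8.0
    mean_priors: dict[str, tuple[float, float]] = field(
        default_factory=_default_mean_priors
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_nm < 0:
            raise RetinotuneError("noise sigma must be >= 0")
        if self.width_sws2a_deg <= 0 or self.width_sws2b_deg <= 0:
            raise RetinotuneError("fluctuation widths must be positive")
        missing = [t for t in self.true_model.terms if t not in self.mean_priors]
        if missing:
            raise RetinotuneError(f"no mean prior for generating terms: {missing}")

    def width_for(self, paralog: str) -> float:
        return self.width_sws2b_deg if paralog == "Sws2b" else self.width_sws2a_deg


def _registry_kinds() -> dict[str, str]:
    return {d.name: d.kind for d in default_registry()}


def _draw_pigment(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[dict[str, float], float, float]:
    """One pigment's parameter means, noise draw, and implied λ_max."""
    for _ in range(100):
        means = {
            name: float(rng.normal(loc, scale))
            for name, (loc, scale) in spec.mean_priors.items()
        }
        # scale the same standard-normal draw so datasets with different
        # sigma but one seed share means and standardized noise
        noise = float(rng.standard_normal()) * spec.noise_sigma_nm
        lam = spec.true_model.intercept + sum(
            c * means[t]
            for t, c in zip(spec.true_model.terms, spec.true_model.coefficients)
        ) + noise
        if 300.0 <= lam <= 650.0:
            return means, noise, lam
    raise RetinotuneError("could not draw a λ_max inside the sanity window")


def synth_median_table(spec: SyntheticSpec) -> tuple[PigmentDataset, dict]:
    """Generate a modelling table with known generating model.

    Returns the dataset (each record carries its parameter means as the
    median summary — the table is *defined* at the summary level) and a
    ground-truth document with the model, means and noise draws.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[PigmentRecord] = []
    truth_rows = []
    for species, paralog in spec.layout:
        means, noise, lam = _draw_pigment(spec, rng)
        summary = FeatureSummary(medians=dict(means), frame_count=spec.n_frames)
        records.append(PigmentRecord(species, paralog, lam, summary))
        truth_rows.append(
            {"species": species, "paralog": paralog, "means": means,
             "noise_nm": noise, "lambda_max_nm": lam}
        )
    truth = {
        "model": spec.true_model.to_dict(),
        "noise_sigma_nm": spec.noise_sigma_nm,
        "seed": spec.seed,
        "pigments": truth_rows,
    }
    return PigmentDataset(records), truth


def synth_angle_series(
    spec: SyntheticSpec,
    parameters: Sequence[str] | None = None,
) -> tuple[dict[str, FeatureSeries], PigmentDataset, dict]:
    """Per-frame fluctuations around each pigment's parameter means.

    Torsions: wrapped normal about the mean with the paralog-group width.
    Geometric angles: normal truncated to [0°, 180°].  Returns the series
    keyed by pigment id, the dataset whose λ_max derives from the *means*
    (not the finite-sample medians), and the ground truth.
    """
    dataset, truth = synth_median_table(spec)
    kinds = _registry_kinds()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    series: dict[str, FeatureSeries] = {}
    for record in dataset:
        width = spec.width_for(record.paralog)
        values: dict[str, np.ndarray] = {}
        for name, mean in record.feature_summary.medians.items():
            if parameters is not None and name not in parameters:
                continue
            kind = kinds.get(name, "geometric")
            if kind == "torsion":
                values[name] = wrap_degrees(
                    rng.normal(mean, width, size=spec.n_frames)
                )
            else:
                a, b = (0.0 - mean) / width, (180.0 - mean) / width
                values[name] = truncnorm.rvs(
                    a, b, loc=mean, scale=width, size=spec.n_frames,
                    random_state=rng,
                )
        series[record.pigment_id] = FeatureSeries(record.pigment_id, values, kinds)
    return series, dataset, truth


# ---------------------------------------------------------------------------
# inverse geometry


def synth_coordinates(
    definition: AngleDefinition, target: float
) -> dict[str, np.ndarray]:
    """A minimal frame whose evaluated parameter equals ``target`` exactly.

    Geometric targets must lie in [0, 180]; torsion targets in (−180, 180].
    """
    t = float(target)
    if definition.kind == "geometric":
        if not (0.0 <= t <= 180.0):
            raise RetinotuneError(f"geometric target {t} outside [0, 180]")
        a1, a2, a3 = definition.atoms
        rad = np.radians(t)
        return {
            a1: np.array([1.5, 0.0, 0.0]),
            a2: np.array([0.0, 0.0, 0.0]),
            a3: 1.5 * np.array([np.cos(rad), np.sin(rad), 0.0]),
        }
    if not (-180.0 < t <= 180.0):
        raise RetinotuneError(f"torsion target {t} outside (-180, 180]")
    a1, a2, a3, a4 = definition.atoms
    p1 = np.array([-0.7, 1.3, 0.0])
    p2 = np.array([0.0, 0.0, 0.0])
    p3 = np.array([1.5, 0.0, 0.0])
    theta = np.radians(110.0)  # bond angle p2-p3-p4, arbitrary non-degenerate
    for sign in (+1.0, -1.0):
        phi = np.radians(sign * t)
        p4 = p3 + 1.5 * np.array(
            [np.cos(np.pi - theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
        )
        got = dihedral(p1, p2, p3, p4)
        if abs(wrap_degrees(got - t)) < 1e-9:
            return {a1: p1, a2: p2, a3: p3, a4: p4}
    raise RetinotuneError(f"failed to realise torsion target {t}")  # pragma: no cover


def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float
) -> np.ndarray:
    """NeRF placement: atom bonded to c with bond angle b-c-d and dihedral a-b-c-d."""
    th, ph = np.radians(theta), np.radians(phi)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(th), r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# z-matrix for an idealized LYS+RET moiety: (atom, (a, b, c), r, theta, phi).
# Geometry is plausible (trans polyene, 11-cis kink, gauche lysine chain),
# not energy-minimised; it exists to exercise the extraction path.
_ZMATRIX: tuple[tuple[str, tuple[str, str, str], float, float, float], ...] = (
    ("C4", ("C1", "C2", "C3"), 1.54, 111.0, 55.0),
    ("C5", ("C2", "C3", "C4"), 1.50, 111.0, -55.0),
    ("C6", ("C3", "C4", "C5"), 1.35, 120.0, 30.0),
    ("C7", ("C4", "C5", "C6"), 1.46, 125.0, -170.0),
    ("C8", ("C5", "C6", "C7"), 1.34, 125.0, -40.0),
    ("C9", ("C6", "C7", "C8"), 1.46, 120.0, 178.0),
    ("C10", ("C7", "C8", "C9"), 1.35, 120.0, 179.0),
    ("C11", ("C8", "C9", "C10"), 1.46, 120.0, 178.0),
    ("C12", ("C9", "C10", "C11"), 1.34, 122.0, 179.0),
    ("C13", ("C10", "C11", "C12"), 1.46, 120.0, -8.0),
    ("C14", ("C11", "C12", "C13"), 1.35, 122.0, 178.0),
    ("C15", ("C12", "C13", "C14"), 1.46, 120.0, 179.0),
    ("NZ", ("C13", "C14", "C15"), 1.28, 121.0, 178.0),
    ("CE", ("C14", "C15", "NZ"), 1.47, 122.0, 176.0),
    ("CD", ("C15", "NZ", "CE"), 1.52, 112.0, 178.0),
    ("CG", ("NZ", "CE", "CD"), 1.52, 111.0, 65.0),
    ("CB", ("CE", "CD", "CG"), 1.52, 111.0, 178.0),
    ("CA", ("CD", "CG", "CB"), 1.52, 111.0, 179.0),
    ("N", ("CG", "CB", "CA"), 1.47, 110.0, 60.0),
    ("C", ("CG", "CB", "CA"), 1.52, 109.0, -65.0),
    ("O", ("CB", "CA", "C"), 1.23, 120.0, 0.0),
    ("C16", ("C3", "C2", "C1"), 1.54, 109.0, 60.0),
    ("C17", ("C3", "C2", "C1"), 1.54, 109.0, -60.0),
    ("C18", ("C3", "C4", "C5"), 1.54, 109.0, 70.0),
    ("C19", ("C7", "C8", "C9"), 1.50, 117.0, -5.0),
    ("C20", ("C11", "C12", "C13"), 1.50, 117.0, 12.0),
)


def idealized_frame() -> dict[str, np.ndarray]:
    """Idealized 3-D coordinates (Å) for all 29 LYS+RET heavy atoms."""
    coords: dict[str, np.ndarray] = {
        "C1": np.array([0.0, 0.0, 0.0]),
        "C2": np.array([1.54, 0.0, 0.0]),
        "C3": np.array([1.54, 0.0, 0.0])
        + 1.54 * np.array([np.cos(np.radians(68.0)), np.sin(np.radians(68.0)), 0.0]),
    }
    for atom, (a, b, c), r, theta, phi in _ZMATRIX:
        coords[atom] = _place(coords[a], coords[b], coords[c], r, theta, phi)
    return coords


def synth_trajectory(
    n_frames: int = 100,
    jitter_angstrom: float = 0.05,
    seed: int = 0,
    frame_interval_ps: float = 10.0,
    pigment_id: str | None = None,
) -> Trajectory:
    """Idealized moiety plus iid Gaussian coordinate jitter per frame."""
    if n_frames < 1:
        raise RetinotuneError("need at least one frame")
    frame = idealized_frame()
    names = tuple(frame)
    base = np.stack([frame[a] for a in names])
    rng = np.random.default_rng(seed)
    coords = base[None, :, :] + rng.normal(
        0.0, jitter_angstrom, size=(n_frames, len(names), 3)
    )
    return Trajectory(
        atom_names=names,
        coords=coords,
        frame_interval_ps=frame_interval_ps,
        pigment_id=pigment_id,
    )


# ---------------------------------------------------------------------------
# pipeline recovery experiment

#: Default inert companions to the generating terms: the other members of
#: the seven-parameter shortlist used in the published selection.
DEFAULT_INERT_TERMS: tuple[str, ...] = (
    "Torsion 9",
    "Torsion 10",
    "Torsion 11",
    "Angle 1",
)


@dataclass
class RecoveryResult:
    """Aggregate outcome of repeated screen → search → fit runs."""

    reps: int
    exact_recovery_rate: float
    containment_rate: float
    coef_bias: dict[str, float]
    coef_rmse: dict[str, float]
    intercept_bias: float
    mean_abs_coef_bias: float


def parameter_recovery_experiment(
    spec: SyntheticSpec,
    reps: int,
    seed: int,
    shortlist: Sequence[str] | None = None,
) -> RecoveryResult:
    """Run the full selection pipeline on ``reps`` independent tables.

    Each replicate draws a fresh table from ``spec`` (re-seeded from
    ``seed``), screens the candidate parameters by r², ranks every subset
    of the shortlist by BIC, and refits the true term set to measure
    coefficient bias.  ``shortlist`` defaults to the generating terms plus
    four inert companions (seven candidates in all).
    """
    if reps < 1:
        raise RetinotuneError("reps must be >= 1")
    true_terms = set(spec.true_model.terms)
    if shortlist is None:
        shortlist = tuple(spec.true_model.terms) + tuple(
            t for t in DEFAULT_INERT_TERMS if t not in true_terms
        )
    all_params = list(spec.mean_priors)
    non_candidates = [p for p in all_params if p not in shortlist]
    exact = contained = 0
    coef_errors: dict[str, list[float]] = {t: [] for t in spec.true_model.terms}
    intercept_errors: list[float] = []
    for i in range(reps):
        rep_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        dataset, _ = synth_median_table(replace(spec, seed=rep_seed))
        screen = correlation_screen(
            dataset, exclude=non_candidates, shortlist_size=len(shortlist)
        )
        search = exhaustive_subset_search(dataset, screen.shortlist)
        selected = set(search.best.terms)
        if selected == true_terms:
            exact += 1
        if true_terms <= selected:
            contained += 1
        refit = fit_ols(dataset, spec.true_model.terms)
        intercept_errors.append(refit.intercept - spec.true_model.intercept)
        for t, c_true, c_hat in zip(
            spec.true_model.terms, spec.true_model.coefficients, refit.coefficients
        ):
            coef_errors[t].append(c_hat - c_true)
    bias = {t: float(np.mean(v)) for t, v in coef_errors.items()}
    rmse = {t: float(np.sqrt(np.mean(np.square(v)))) for t, v in coef_errors.items()}
    return RecoveryResult(
        reps=reps,
        exact_recovery_rate=exact / reps,
        containment_rate=contained / reps,
        coef_bias=bias,
        coef_rmse=rmse,
        intercept_bias=float(np.mean(intercept_errors)),
        mean_abs_coef_bias=float(np.mean([abs(b) for b in bias.values()])),
    )
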