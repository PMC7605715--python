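"""End-to-end pipeline with reproducible configuration.

A single flat YAML document drives a full run: load (or synthesise) the
modelling table, screen parameters, rank all subsets by BIC, validate the
selected model by both leave-one-out schemes, and write every artifact with
the SHA-256 hash of the configuration that produced it, so a rerun with an
identical config is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .exceptions import RetinotuneError
from .io import PigmentDataset, load_reference_pigments, read_median_table, read_pigment_table
from .selection import (
    correlation_screen,
    default_screen_exclusions,
    exhaustive_subset_search,
)
from .synthetic import SyntheticSpec, synth_median_table
from .validation import full_model_report, loo_by_pigment, loo_by_species

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat, human-editable run configuration.

    ``median_table`` is a path, or the literal string ``"synthetic"`` to
    generate a table from :class:`SyntheticSpec` defaults (with
    ``synthetic_sigma_nm`` / ``synthetic_frames`` overrides).  Relative
    paths are resolved against the config file's directory.
    """

    out_dir: str = "retinotune_out"
    median_table: str = "synthetic"
    pigment_table: str | None = None
    registry: str | None = None
    exclude: list[str] = field(
        default_factory=lambda: list(default_screen_exclusions())
    )
    shortlist_size: int = 7
    bic_window: float = 2.0
    rounding: int = 2
    seed: int = 0
    synthetic_sigma_nm: float = 6.8
    synthetic_frames: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise RetinotuneError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        base = path.parent
        for attr in ("median_table", "pigment_table", "registry", "out_dir"):
            val = getattr(cfg, attr)
            if val and val != "synthetic" and not Path(val).is_absolute():
                setattr(cfg, attr, str(base / val))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_json(path: Path, payload: dict, config_hash: str) -> None:
    payload = {"config_hash": config_hash, **payload}
    path.write_text(json.dumps(payload, indent=2) + "\n")


def _load_dataset(config: RunConfig, out: Path, config_hash: str) -> PigmentDataset:
    if config.median_table == "synthetic":
        spec = SyntheticSpec(
            seed=config.seed,
            noise_sigma_nm=config.synthetic_sigma_nm,
            n_frames=config.synthetic_frames,
        )
        dataset, truth = synth_median_table(spec)
        csv_path = out / "synthetic_median_table.csv"
        with open(csv_path, "w") as fh:
            fh.write(f"# config_hash: {config_hash}\n")
            dataset.to_frame().to_csv(fh, index=False)
        _write_json(out / "synthetic_ground_truth.json", truth, config_hash)
        return dataset
    pigments = (
        read_pigment_table(config.pigment_table)
        if config.pigment_table
        else load_reference_pigments()
    )
    return read_median_table(config.median_table, pigment_table=pigments)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run screen → subset search → validation; return artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    artifacts: dict[str, Path] = {}

    try:
        dataset = _load_dataset(config, out, h)
    except Exception as exc:
        raise RetinotuneError(f"stage 'load': {exc}") from exc

    try:
        screen = correlation_screen(
            dataset, exclude=config.exclude, shortlist_size=config.shortlist_size
        )
        _write_json(
            out / "screen.json",
            {
                "r2": {k: round(v, 6) for k, v in screen.r2.items()},
                "ranked": screen.ranked,
                "shortlist": screen.shortlist,
                "excluded": screen.excluded,
                "dropped_constant": screen.dropped_constant,
            },
            h,
        )
        artifacts["screen"] = out / "screen.json"
    except Exception as exc:
        raise RetinotuneError(f"stage 'screen': {exc}") from exc

    try:
        search = exhaustive_subset_search(
            dataset, screen.shortlist, bic_window=config.bic_window
        )
        _write_json(
            out / "subset_search.json",
            {
                "n_models": len(search.models),
                "best": search.best.to_dict(),
                "window": [m.to_dict() for m in search.window],
                "window_delta": search.window_delta,
            },
            h,
        )
        best = search.best
        _write_json(out / "best_model.json", best.to_dict(), h)
        artifacts["subset_search"] = out / "subset_search.json"
        artifacts["best_model"] = out / "best_model.json"
    except Exception as exc:
        raise RetinotuneError(f"stage 'subset_search': {exc}") from exc

    try:
        full = full_model_report(dataset, best.terms)
        _write_json(out / "validation_full.json", full.to_dict(), h)
        loo = loo_by_pigment(dataset, best.terms)
        _write_json(out / "validation_loo_pigment.json", loo.to_dict(), h)
        artifacts["validation_full"] = out / "validation_full.json"
        artifacts["validation_loo_pigment"] = out / "validation_loo_pigment.json"
        species_reports = {}
        for species in sorted(dataset.species_with_both_paralogs()):
            rep = loo_by_species(
                dataset,
                species,
                exclude=config.exclude,
                shortlist_size=config.shortlist_size,
                bic_window=config.bic_window,
            )
            species_reports[species] = rep.to_dict()
        _write_json(out / "validation_loo_species.json", {"folds": species_reports}, h)
        artifacts["validation_loo_species"] = out / "validation_loo_species.json"
    except Exception as exc:
        raise RetinotuneError(f"stage 'validate': {exc}") from exc

    _write_json(
        out / "run_log.json",
        {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "artifacts": {k: str(v) for k, v in artifacts.items()},
            "n_pigments": len(dataset),
            "selected_terms": list(best.terms),
        },
        h,
    )
    artifacts["run_log"] = out / "run_log.json"
    return artifacts
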