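"""On-disk representations: trajectories, pigment tables, median tables.

Trajectories of the LYS+RET moiety are exchanged in three plain-text
dialects:

* multi-MODEL PDB (``MODEL``/``ENDMDL`` blocks, one per frame),
* XYZ (per-frame blocks: atom count, comment, ``name x y z`` lines),
* long-format CSV with header ``frame,atom,x,y,z``.

Coordinates are in Å and frames are 0-indexed throughout.  Retinal carbons
are named ``C1``–``C20``; lysine heavy atoms use PDB names, with the
Schiff-base nitrogen stored as ``NZ`` (the sketch label ``N+`` is accepted
as an alias on input).  Parsers never silently drop frames or atoms: an
inconsistent frame raises a parse error naming the first offender.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import TableValidationError, TrajectoryParseError
from .features import FeatureSummary
from .geometry import LYS_RET_ATOMS, default_registry

__all__ = [
    "Trajectory",
    "PigmentRecord",
    "PigmentDataset",
    "read_trajectory",
    "write_trajectory",
    "read_pigment_table",
    "read_median_table",
    "load_reference_pigments",
    "canonical_atom_name",
]

_ALIASES = {"N+": "NZ"}

#: Paralog labels accepted in pigment tables.
PARALOGS = ("Sws2a", "Sws2b", "Sws2")

LAMBDA_SANITY_NM = (300.0, 650.0)


def canonical_atom_name(name: str) -> str:
    """Map accepted aliases (``N+``) onto canonical PDB-style names."""
    return _ALIASES.get(name.strip(), name.strip())


@dataclass
class Trajectory:
    """Ordered frames of named 3-D coordinates (Å) for one simulation."""

    atom_names: tuple[str, ...]
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval_ps: float | None = None
    pigment_id: str | None = None

    def __post_init__(self) -> None:
        self.atom_names = tuple(canonical_atom_name(a) for a in self.atom_names)
        if len(set(self.atom_names)) != len(self.atom_names):
            raise TrajectoryParseError("duplicate atom names within a frame")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.atom_names), 3):
            raise TrajectoryParseError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{len(self.atom_names)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryParseError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def frame_mapping(self, t: int) -> dict[str, np.ndarray]:
        """Frame ``t`` as an atom-name → 3-vector mapping."""
        return dict(zip(self.atom_names, self.coords[t]))


def _check_names(names: Sequence[str], strict: bool) -> None:
    if strict:
        unknown = [a for a in names if a not in LYS_RET_ATOMS]
        if unknown:
            raise TrajectoryParseError(
                f"unknown atom labels {unknown}; expected LYS+RET heavy atoms "
                f"{list(LYS_RET_ATOMS)}"
            )


def _infer_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext == ".pdb":
        return "pdb-multimodel"
    if ext == ".xyz":
        return "xyz"
    if ext == ".csv":
        return "csv"
    raise TrajectoryParseError(f"cannot infer trajectory format from {path.name!r}")


def read_trajectory(
    path: str | Path, format: str | None = None, strict_names: bool = True
) -> Trajectory:
    """Read a trajectory from PDB (multi-MODEL), XYZ or long-format CSV."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "pdb-multimodel":
        traj = _read_pdb(path)
    elif fmt == "xyz":
        traj = _read_xyz(path)
    elif fmt == "csv":
        traj = _read_csv(path)
    else:
        raise TrajectoryParseError(f"unknown trajectory format {fmt!r}")
    _check_names(traj.atom_names, strict_names)
    return traj


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "pdb-multimodel":
        _write_pdb(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    elif fmt == "csv":
        _write_csv(traj, path)
    else:
        raise TrajectoryParseError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# multi-MODEL PDB


def _frames_consistent(frames: list[tuple[list[str], list[list[float]]]]) -> tuple[str, ...]:
    names0 = tuple(frames[0][0])
    for t, (names, _) in enumerate(frames):
        if tuple(names) != names0:
            extra = sorted(set(names) - set(names0))
            missing = sorted(set(names0) - set(names))
            raise TrajectoryParseError(
                f"frame {t} has an inconsistent atom set "
                f"(missing {missing or '[]'}, unexpected {extra or '[]'})"
            )
    return names0


def _read_pdb(path: Path) -> Trajectory:
    frames: list[tuple[list[str], list[list[float]]]] = []
    names: list[str] = []
    xyz: list[list[float]] = []
    in_model = False
    seen_model_records = False
    for raw in path.read_text().splitlines():
        rec = raw[:6].strip()
        if rec == "MODEL":
            seen_model_records = True
            in_model = True
            names, xyz = [], []
        elif rec == "ENDMDL":
            in_model = False
            frames.append((names, xyz))
        elif rec in ("ATOM", "HETATM"):
            if not seen_model_records and not in_model:
                in_model = True  # single-model file without MODEL records
                names, xyz = [], []
            try:
                name = canonical_atom_name(raw[12:16])
                x, y, z = float(raw[30:38]), float(raw[38:46]), float(raw[46:54])
            except ValueError as exc:
                raise TrajectoryParseError(
                    f"frame {len(frames)}: malformed coordinate record {raw!r}"
                ) from exc
            names.append(name)
            xyz.append([x, y, z])
    if not seen_model_records and names:
        frames.append((names, xyz))
    if not frames:
        raise TrajectoryParseError(f"{path.name}: no MODEL blocks or atom records")
    atom_names = _frames_consistent(frames)
    coords = np.array([f[1] for f in frames], dtype=float)
    return Trajectory(atom_names, coords)


def _write_pdb(traj: Trajectory, path: Path) -> None:
    lines: list[str] = []
    for t in range(traj.n_frames):
        lines.append(f"MODEL     {t + 1:4d}")
        for i, name in enumerate(traj.atom_names):
            x, y, z = traj.coords[t, i]
            element = name[0]
            # left-justify in cols 13-16 as is conventional for short names
            lines.append(
                f"HETATM{i + 1:5d} {name:<4s} LRT A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ frame blocks


def _read_xyz(path: Path) -> Trajectory:
    lines = path.read_text().splitlines()
    frames: list[tuple[list[str], list[list[float]]]] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"frame {len(frames)}: expected atom count, got {lines[i]!r}"
            ) from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise TrajectoryParseError(
                f"frame {len(frames)}: truncated block ({len(block)}/{n} atoms)"
            )
        names, xyz = [], []
        for line in block:
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"frame {len(frames)}: malformed atom line {line!r}"
                )
            names.append(canonical_atom_name(parts[0]))
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append((names, xyz))
        i += 2 + n
    if not frames:
        raise TrajectoryParseError(f"{path.name}: empty XYZ file")
    atom_names = _frames_consistent(frames)
    return Trajectory(atom_names, np.array([f[1] for f in frames], dtype=float))


def _write_xyz(traj: Trajectory, path: Path) -> None:
    lines: list[str] = []
    for t in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"frame {t}")
        for i, name in enumerate(traj.atom_names):
            x, y, z = traj.coords[t, i]
            lines.append(f"{name} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# long-format CSV (frame, atom, x, y, z)


def _read_csv(path: Path) -> Trajectory:
    df = pd.read_csv(path)
    required = {"frame", "atom", "x", "y", "z"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise TrajectoryParseError(
            f"CSV trajectory missing columns {sorted(missing_cols)}"
        )
    if df.empty:
        raise TrajectoryParseError(f"{path.name}: empty CSV trajectory")
    df["atom"] = df["atom"].map(canonical_atom_name)
    frames = sorted(df["frame"].unique())
    names0: tuple[str, ...] | None = None
    coords = []
    for t in frames:
        sub = df[df["frame"] == t]
        names = tuple(sub["atom"])
        if names0 is None:
            names0 = names
        elif set(names) != set(names0):
            missing = sorted(set(names0) - set(names))
            extra = sorted(set(names) - set(names0))
            raise TrajectoryParseError(
                f"frame {t} has an inconsistent atom set "
                f"(missing {missing or '[]'}, unexpected {extra or '[]'})"
            )
        sub = sub.set_index("atom").loc[list(names0)]
        coords.append(sub[["x", "y", "z"]].to_numpy(float))
    return Trajectory(tuple(names0), np.stack(coords))


def _write_csv(traj: Trajectory, path: Path) -> None:
    rows = []
    for t in range(traj.n_frames):
        for i, name in enumerate(traj.atom_names):
            x, y, z = traj.coords[t, i]
            rows.append((t, name, x, y, z))
    pd.DataFrame(rows, columns=["frame", "atom", "x", "y", "z"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# pigment metadata and median tables


@dataclass
class PigmentRecord:
    """One photopigment: species, paralog and experimental λ_max (nm)."""

    species: str
    paralog: str
    lambda_max_exp: float
    feature_summary: FeatureSummary | None = None

    def __post_init__(self) -> None:
        if self.paralog not in PARALOGS:
            raise TableValidationError(
                f"{self.species}: paralog must be one of {PARALOGS}, got {self.paralog!r}"
            )
        lo, hi = LAMBDA_SANITY_NM
        if not (lo <= float(self.lambda_max_exp) <= hi):
            raise TableValidationError(
                f"{self.species} {self.paralog}: λ_max {self.lambda_max_exp} nm "
                f"outside sanity window [{lo}, {hi}]"
            )

    @property
    def pigment_id(self) -> str:
        return f"{self.species} {self.paralog}"


class PigmentDataset:
    """Ordered collection of pigment records, unique by (species, paralog)."""

    def __init__(self, records: Iterable[PigmentRecord]):
        self.records = list(records)
        keys = [(r.species, r.paralog) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise TableValidationError(f"duplicate (species, paralog) rows: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PigmentRecord]:
        return iter(self.records)

    def get(self, species: str, paralog: str) -> PigmentRecord:
        for r in self.records:
            if r.species == species and r.paralog == paralog:
                return r
        raise KeyError((species, paralog))

    def species_with_both_paralogs(self) -> list[str]:
        """Species represented by both an Sws2a and an Sws2b record."""
        by_species: dict[str, set[str]] = {}
        for r in self.records:
            by_species.setdefault(r.species, set()).add(r.paralog)
        return [s for s, p in by_species.items() if {"Sws2a", "Sws2b"} <= p]

    def drop_species(self, species: str) -> "PigmentDataset":
        return PigmentDataset(r for r in self.records if r.species != species)

    def drop_index(self, i: int) -> "PigmentDataset":
        return PigmentDataset(r for j, r in enumerate(self.records) if j != i)

    def lambda_max(self) -> np.ndarray:
        return np.array([r.lambda_max_exp for r in self.records], dtype=float)

    def medians_frame(self) -> pd.DataFrame:
        """Median matrix (pigments × parameters) from attached summaries."""
        rows, index = [], []
        for r in self.records:
            if r.feature_summary is None:
                raise TableValidationError(
                    f"{r.pigment_id}: no feature summary attached"
                )
            rows.append(r.feature_summary.medians)
            index.append(r.pigment_id)
        return pd.DataFrame(rows, index=index)

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "paralog": [r.paralog for r in self.records],
                "lambda_max_nm": [r.lambda_max_exp for r in self.records],
            }
        )
        if all(r.feature_summary is not None for r in self.records) and self.records:
            med = self.medians_frame().reset_index(drop=True)
            base = pd.concat([base, med], axis=1)
        return base

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_pigment_table(path: str | Path) -> PigmentDataset:
    """Read a species/paralog/λ_max table (CSV)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    lam_col = cols.get("lambda_max_nm") or cols.get("lambda_max")
    if "species" not in cols or "paralog" not in cols or lam_col is None:
        raise TableValidationError(
            "pigment table needs columns species, paralog, lambda_max_nm"
        )
    lam = pd.to_numeric(df[lam_col], errors="coerce")
    if lam.isna().any():
        bad = df.loc[lam.isna(), cols["species"]].tolist()
        raise TableValidationError(f"non-numeric λ_max for rows: {bad}")
    records = [
        PigmentRecord(str(s), str(p), float(l))
        for s, p, l in zip(df[cols["species"]], df[cols["paralog"]], lam)
    ]
    return PigmentDataset(records)


def read_median_table(
    path: str | Path,
    pigment_table: PigmentDataset | None = None,
    parameters: Sequence[str] | None = None,
    expected_rows: int | None = None,
) -> PigmentDataset:
    """Read a per-pigment median table (CSV or XLSX) into a dataset.

    The table must have ``species`` and ``paralog`` columns plus one column
    per parameter (default: the 19 names of the default registry).  λ_max
    is taken from a ``lambda_max_nm`` column if present, otherwise joined
    from ``pigment_table`` by (species, paralog).  ``expected_rows``
    enforces a strict row count.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    params = list(parameters) if parameters is not None else list(
        default_registry().names
    )
    if df.empty:
        return PigmentDataset([])
    missing = [p for p in params if p not in df.columns]
    if missing:
        raise TableValidationError(f"median table missing parameter columns {missing}")
    for col in ("species", "paralog"):
        if col not in df.columns:
            raise TableValidationError(f"median table missing column {col!r}")
    if expected_rows is not None and len(df) != expected_rows:
        raise TableValidationError(
            f"median table has {len(df)} rows; expected {expected_rows}"
        )
    records = []
    frame_counts = df["frame_count"] if "frame_count" in df.columns else None
    for i, row in df.iterrows():
        species, paralog = str(row["species"]), str(row["paralog"])
        if "lambda_max_nm" in df.columns and pd.notna(row["lambda_max_nm"]):
            lam = float(row["lambda_max_nm"])
        elif pigment_table is not None:
            lam = pigment_table.get(species, paralog).lambda_max_exp
        else:
            raise TableValidationError(
                f"row {i} ({species} {paralog}): no λ_max column and no pigment table"
            )
        medians = {p: float(row[p]) for p in params}
        summary = FeatureSummary(
            medians=medians,
            frame_count=int(frame_counts.iloc[i]) if frame_counts is not None else 0,
            auc_rmsf=float(row["auc_rmsf"]) if "auc_rmsf" in df.columns else None,
        )
        records.append(PigmentRecord(species, paralog, lam, summary))
    return PigmentDataset(records)


def load_reference_pigments() -> PigmentDataset:
    """The bundled table of 11 teleost Sws2 pigments with measured λ_max."""
    ref = importlib.resources.files("retinotune") / "data" / "sws2_pigments.csv"
    with importlib.resources.as_file(ref) as p:
        return read_pigment_table(p)
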