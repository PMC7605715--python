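"""Internal-coordinate geometry of the chromophore + lysine (LYS+RET) moiety.

The dark-state conformation of 11-*cis* retinal, covalently bound through a
Schiff base to lysine-296 of the opsin, is summarised here by 19 named
internal coordinates: 15 torsion (dihedral) angles over four bonded heavy
atoms and 4 geometric bond angles over three atoms.  Three of the
definitions are fixed by the published analysis —

* ``Torsion 3``  = C15–C14–C13–C20 (the C13 methyl torsion),
* ``Torsion 12`` = C19–C9–C8–C7   (the C9 methyl torsion),
* ``Angle 3``    = C3–C7–C8,

and ``Angle 2`` is the geometric angle at the Schiff-base nitrogen
(CE–NZ–C15 of K296).  The remaining entries of the default registry are
filled from standard retinal backbone connectivity (β-ionone ring C1–C6,
conjugated chain C6…C15, methyls C16–C20, lysine side chain CB–CG–CD–CE–NZ)
and are flagged ``inferred=True``: they are reasonable stand-ins, not
ground truth, and can be overridden with a user registry file.

Torsions follow the IUPAC sign convention: 0° is *cis* (eclipsed), the sign
is given by the right-hand rule about the p2→p3 axis, and values lie in
(−180°, 180°].  Geometric angles lie in [0°, 180°].  Degenerate geometry
(zero-length bond, collinear torsion axis) raises
:class:`~retinotune.exceptions.DegenerateGeometryError` rather than
returning NaN, because silent NaNs would corrupt downstream medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .exceptions import DegenerateGeometryError, MissingAtomError, RetinotuneError

__all__ = [
    "AngleDefinition",
    "AngleRegistry",
    "bond_angle",
    "dihedral",
    "evaluate_registry",
    "default_registry",
    "RETINAL_ATOMS",
    "LYSINE_ATOMS",
    "LYS_RET_ATOMS",
]

#: Retinal heavy atoms: ring C1-C6, polyene chain C7-C15, methyls C16-C20.
RETINAL_ATOMS: tuple[str, ...] = tuple(f"C{i}" for i in range(1, 21))

#: Lysine-296 heavy atoms; NZ is the Schiff-base nitrogen (drawn "N+" in
#: chemical sketches; the alias is normalised at the I/O layer).
LYSINE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ")

LYS_RET_ATOMS: tuple[str, ...] = RETINAL_ATOMS + LYSINE_ATOMS

_EPS = 1e-12


@dataclass(frozen=True)
class AngleDefinition:
    """One named internal coordinate of the LYS+RET moiety."""

    name: str
    kind: str  # "torsion" | "geometric"
    atoms: tuple[str, ...]
    inferred: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("torsion", "geometric"):
            raise RetinotuneError(f"unknown angle kind {self.kind!r}")
        need = 4 if self.kind == "torsion" else 3
        if len(self.atoms) != need:
            raise RetinotuneError(
                f"{self.name}: {self.kind} angle needs {need} atoms, got {len(self.atoms)}"
            )
        unknown = [a for a in self.atoms if a not in LYS_RET_ATOMS]
        if unknown:
            raise RetinotuneError(
                f"{self.name}: atoms {unknown} are not LYS+RET heavy atoms"
            )


@dataclass
class AngleRegistry:
    """Ordered collection of angle definitions with unique names."""

    definitions: tuple[AngleDefinition, ...]
    source: str = "user-config"

    def __post_init__(self) -> None:
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RetinotuneError(f"duplicate angle names in registry: {dupes}")

    def __iter__(self) -> Iterator[AngleDefinition]:
        return iter(self.definitions)

    def __len__(self) -> int:
        return len(self.definitions)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.definitions)

    def get(self, name: str) -> AngleDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise KeyError(name)

    def subset(self, names: Iterable[str]) -> "AngleRegistry":
        wanted = list(names)
        return AngleRegistry(tuple(self.get(n) for n in wanted), source=self.source)

    # -- plain-text config round trip -------------------------------------
    # One definition per line: ``name | kind | atom,atom,... [| inferred]``

    def to_config(self, path: str | Path) -> None:
        lines = ["# name | kind | atoms | flags"]
        for d in self.definitions:
            flag = " | inferred" if d.inferred else ""
            lines.append(f"{d.name} | {d.kind} | {','.join(d.atoms)}{flag}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "AngleRegistry":
        defs = []
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("|")]
            if len(parts) < 3:
                raise RetinotuneError(f"malformed registry line: {raw!r}")
            name, kind, atoms = parts[0], parts[1], tuple(parts[2].split(","))
            inferred = "inferred" in parts[3:]
            defs.append(
                AngleDefinition(name, kind, tuple(a.strip() for a in atoms), inferred)
            )
        return cls(tuple(defs), source=str(path))


def _as_vec(p: Sequence[float]) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise RetinotuneError(f"expected a 3-vector, got shape {v.shape}")
    return v


def bond_angle(p1: Sequence[float], p2: Sequence[float], p3: Sequence[float]) -> float:
    """Geometric angle at vertex ``p2`` between rays p2→p1 and p2→p3, degrees.

    Uses the atan2(‖v1×v2‖, v1·v2) form, which is numerically stable near
    0° and 180°.  Returns a value in [0, 180].
    """
    v1 = _as_vec(p1) - _as_vec(p2)
    v2 = _as_vec(p3) - _as_vec(p2)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < _EPS or n2 < _EPS:
        raise DegenerateGeometryError("zero-length bond vector at angle vertex")
    cross = np.cross(v1, v2)
    return float(np.degrees(np.arctan2(np.linalg.norm(cross), float(v1 @ v2))))


def dihedral(
    p1: Sequence[float],
    p2: Sequence[float],
    p3: Sequence[float],
    p4: Sequence[float],
) -> float:
    """Signed torsion of plane (p1,p2,p3) vs (p2,p3,p4), degrees in (−180, 180].

    IUPAC convention: 0° for the eclipsed (*cis*) arrangement, positive by
    the right-hand rule about the p2→p3 axis.
    """
    b1 = _as_vec(p2) - _as_vec(p1)
    b2 = _as_vec(p3) - _as_vec(p2)
    b3 = _as_vec(p4) - _as_vec(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _EPS:
        raise DegenerateGeometryError("zero-length torsion axis p2->p3")
    if np.linalg.norm(n1) < _EPS:
        raise DegenerateGeometryError("collinear atoms p1, p2, p3: torsion undefined")
    if np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("collinear atoms p2, p3, p4: torsion undefined")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ b2) / nb2
    ang = float(np.degrees(np.arctan2(y, x)))
    # close the range at +180 rather than -180
    if ang <= -180.0:
        ang += 360.0
    return ang


def evaluate_registry(
    frame: Mapping[str, Sequence[float]], registry: AngleRegistry
) -> dict[str, float]:
    """Evaluate every definition of ``registry`` on a single coordinate frame.

    ``frame`` maps canonical atom names to 3-vectors (Å).  Raises
    :class:`MissingAtomError` naming both the definition and the first
    missing atom.
    """
    out: dict[str, float] = {}
    for d in registry:
        coords = []
        for a in d.atoms:
            if a not in frame:
                raise MissingAtomError(
                    f"{d.name}: atom {a!r} missing from frame "
                    f"(needs {', '.join(d.atoms)})"
                )
            coords.append(frame[a])
        if d.kind == "torsion":
            out[d.name] = dihedral(*coords)
        else:
            out[d.name] = bond_angle(*coords)
    return out


def _default_definitions() -> tuple[AngleDefinition, ...]:
    T = lambda name, atoms, inf: AngleDefinition(name, "torsion", atoms, inf)
    A = lambda name, atoms, inf: AngleDefinition(name, "geometric", atoms, inf)
    return (
        # ring-to-chain and polyene backbone torsions (inferred slots)
        T("Torsion 1", ("C4", "C5", "C6", "C7"), True),
        T("Torsion 2", ("C5", "C6", "C7", "C8"), True),
        T("Torsion 3", ("C15", "C14", "C13", "C20"), False),  # C13-methyl
        T("Torsion 4", ("C6", "C7", "C8", "C9"), True),
        T("Torsion 5", ("C7", "C8", "C9", "C10"), True),
        T("Torsion 6", ("C8", "C9", "C10", "C11"), True),
        T("Torsion 7", ("C9", "C10", "C11", "C12"), True),
        T("Torsion 8", ("C10", "C11", "C12", "C13"), True),  # the 11-cis bond
        T("Torsion 9", ("C11", "C12", "C13", "C14"), True),
        T("Torsion 10", ("C12", "C13", "C14", "C15"), True),
        T("Torsion 11", ("C13", "C14", "C15", "NZ"), True),
        T("Torsion 12", ("C19", "C9", "C8", "C7"), False),  # C9-methyl
        T("Torsion 13", ("C14", "C15", "NZ", "CE"), True),  # Schiff base
        T("Torsion 14", ("C15", "NZ", "CE", "CD"), True),
        T("Torsion 15", ("NZ", "CE", "CD", "CG"), True),
        A("Angle 1", ("C5", "C6", "C7"), True),
        A("Angle 2", ("CE", "NZ", "C15"), True),  # at the Schiff-base N of K296
        A("Angle 3", ("C3", "C7", "C8"), False),
        A("Angle 4", ("C11", "C12", "C13"), True),
    )


def default_registry() -> AngleRegistry:
    """The 19-slot default registry: 15 torsions + 4 geometric angles.

    Entries not pinned down by the published analysis are flagged
    ``inferred``; treat their values as internally consistent coordinates of
    the moiety, not as a reconstruction of the original feature set.
    """
    return AngleRegistry(_default_definitions(), source="paper-default")
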