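"""Coordinate I/O, segment definitions and atom selection.

Structures and trajectories are held in :class:`TrajectoryFrames`, a thin
array-of-frames container: frame-invariant atom metadata (name, element,
chain, residue) plus an ``(n_frames, n_atoms, 3)`` coordinate array in Å.
Multi-model PDB and mmCIF files are read and written through biotite.

Segments — named residue-range selections on a chain, such as the upper and
lower lobes of a Venus-fly-trap domain or individual transmembrane helices —
are described by :class:`SegmentDefinition` and grouped in a
:class:`SegmentLibrary`.  The packaged default library carries the GABA_B
receptor segments used throughout: the GB1 VFTD lobes (LBupper 222–235 +
247–260, LBlower 347–358 + 368–382, author numbering) and the TM4/TM5/TM6
helices of both subunits (GB1 711–731 / 769–789 / 805–825, GB2 598–618 /
655–675 / 692–712).  Residue numbers follow author numbering throughout,
because that is how the ranges are defined on the deposited structures;
the mapping of subunit roles (GB1/GB2) to chain identifiers is left to
configuration since deposited chain labels vary between entries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

import biotite.structure as struc
import biotite.structure.io.pdb as _pdb
import biotite.structure.io.pdbx as _pdbx

from .errors import (
    EmptySelectionError,
    FormatError,
    StructuralInconsistencyError,
)

__all__ = [
    "AtomRecord",
    "TrajectoryFrames",
    "SegmentDefinition",
    "SegmentLibrary",
    "ValidationEntry",
    "ValidationReport",
    "load_structure",
    "write_structure",
    "select_segment",
    "validate_library",
    "default_library",
    "BACKBONE_ATOMS",
]

#: Backbone atom names (heavy + amide/alpha hydrogens) excluded by the
#: SIDE_CHAIN atom mode.
BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)

ATOM_MODES = ("CA_ONLY", "HEAVY", "SIDE_CHAIN")
SUBUNIT_ROLES = ("GB1", "GB2")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame: identity plus a coordinate in Å."""

    atom_id: int
    atom_name: str
    element: str
    chain_id: str
    residue_number: int
    residue_name: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


@dataclass
class TrajectoryFrames:
    """Frames × atoms coordinate block with frame-invariant atom metadata.

    Any provider that yields (metadata arrays, per-frame coordinates) can
    build one of these, so binary-trajectory adapters plug in without the
    rest of the package knowing about their formats.
    """

    atom_id: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1 or self.coords.shape[1] < 1:
            raise ValueError("need at least one frame and one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain NaN or infinity")
        n_atoms = self.coords.shape[1]
        for name in ("atom_id", "atom_name", "element", "chain_id", "res_id", "res_name"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have length n_atoms={n_atoms}")
            setattr(self, name, arr)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom(self, frame: int, index: int) -> AtomRecord:
        """Materialize a single atom of a single frame as an AtomRecord."""
        return AtomRecord(
            atom_id=int(self.atom_id[index]),
            atom_name=str(self.atom_name[index]),
            element=str(self.element[index]),
            chain_id=str(self.chain_id[index]),
            residue_number=int(self.res_id[index]),
            residue_name=str(self.res_name[index]),
            coords=self.coords[frame, index],
        )

    # -- biotite bridge ----------------------------------------------------

    @classmethod
    def from_biotite(cls, stack: struc.AtomArrayStack | struc.AtomArray) -> "TrajectoryFrames":
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        return cls(
            atom_id=np.arange(stack.array_length(), dtype=int),
            atom_name=stack.atom_name.astype(str),
            element=stack.element.astype(str),
            chain_id=stack.chain_id.astype(str),
            res_id=stack.res_id.astype(int),
            res_name=stack.res_name.astype(str),
            coords=np.array(stack.coord, dtype=float),
        )

    def to_biotite(self) -> struc.AtomArrayStack:
        stack = struc.AtomArrayStack(self.n_frames, self.n_atoms)
        stack.coord = np.array(self.coords, dtype=np.float32)
        stack.chain_id = self.chain_id.astype("U4")
        stack.res_id = self.res_id.astype(int)
        stack.res_name = self.res_name.astype("U5")
        stack.atom_name = self.atom_name.astype("U6")
        stack.element = self.element.astype("U2")
        stack.hetero = np.zeros(self.n_atoms, dtype=bool)
        return stack


@dataclass(frozen=True)
class SegmentDefinition:
    """A named residue-range selection on one chain."""

    label: str
    subunit_role: str  # "GB1" | "GB2"
    chain_id: str
    residue_ranges: tuple[tuple[int, int], ...]
    atom_mode: str = "CA_ONLY"

    def __post_init__(self) -> None:
        if self.subunit_role not in SUBUNIT_ROLES:
            raise ValueError(f"subunit_role must be one of {SUBUNIT_ROLES}")
        if self.atom_mode not in ATOM_MODES:
            raise ValueError(f"atom_mode must be one of {ATOM_MODES}")
        ranges = tuple((int(a), int(b)) for a, b in self.residue_ranges)
        if not ranges:
            raise ValueError("residue_ranges must be non-empty")
        for a, b in ranges:
            if a > b:
                raise ValueError(f"range start {a} exceeds end {b}")
        for (a1, b1) in ranges:
            for (a2, b2) in ranges:
                if (a1, b1) != (a2, b2) and a1 <= b2 and a2 <= b1:
                    raise ValueError("residue_ranges overlap")
        object.__setattr__(self, "residue_ranges", ranges)

    @property
    def residue_numbers(self) -> list[int]:
        out: list[int] = []
        for a, b in self.residue_ranges:
            out.extend(range(a, b + 1))
        return out

    def with_chain(self, chain_id: str) -> "SegmentDefinition":
        return replace(self, chain_id=chain_id)


@dataclass
class SegmentLibrary:
    """Labelled collection of segment definitions."""

    entries: dict[str, SegmentDefinition]
    provenance: str = ""

    def __post_init__(self) -> None:
        for label, seg in self.entries.items():
            if label != seg.label:
                raise ValueError(f"library key {label!r} != definition label {seg.label!r}")

    def __getitem__(self, label: str) -> SegmentDefinition:
        return self.entries[label]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def with_chain_roles(self, roles: Mapping[str, str]) -> "SegmentLibrary":
        """Re-map chain ids from a subunit-role → chain mapping (e.g. GB1→A)."""
        remapped = {
            label: seg.with_chain(roles.get(seg.subunit_role, seg.chain_id))
            for label, seg in self.entries.items()
        }
        return SegmentLibrary(remapped, provenance=self.provenance + " (chains remapped)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentLibrary":
        with open(path) as fh:
            return cls._from_mapping(yaml.safe_load(fh), provenance=str(path))

    @classmethod
    def _from_mapping(cls, doc: Mapping, provenance: str) -> "SegmentLibrary":
        entries = {}
        for label, spec in doc["segments"].items():
            entries[label] = SegmentDefinition(
                label=label,
                subunit_role=spec["subunit_role"],
                chain_id=spec.get("chain_id", "?"),
                residue_ranges=tuple(tuple(r) for r in spec["residue_ranges"]),
                atom_mode=spec.get("atom_mode", "CA_ONLY"),
            )
        return cls(entries, provenance=doc.get("provenance", provenance))

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "provenance": self.provenance,
            "segments": {
                label: {
                    "subunit_role": seg.subunit_role,
                    "chain_id": seg.chain_id,
                    "residue_ranges": [list(r) for r in seg.residue_ranges],
                    "atom_mode": seg.atom_mode,
                }
                for label, seg in self.entries.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_library() -> SegmentLibrary:
    """The packaged GABA_B receptor segment library (author numbering)."""
    ref = importlib.resources.files("gpcrvar.data").joinpath("segments.yaml")
    with importlib.resources.as_file(ref) as path:
        return SegmentLibrary.from_yaml(path)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_structure(
    path: str | Path,
    format: str = "auto",
    exclude_hetero: bool = True,
) -> TrajectoryFrames:
    """Read a (multi-model) PDB or mmCIF file into TrajectoryFrames.

    One frame per model.  Water and other hetero records are dropped unless
    ``exclude_hetero=False``.  Alternate locations are resolved by keeping
    the highest-occupancy conformer.  Models that disagree in atom count
    raise :class:`StructuralInconsistencyError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            pdb_file = _pdb.PDBFile.read(str(path))
            stack = _pdb.get_structure(pdb_file, model=None, altloc="occupancy")
        elif fmt in ("mmcif", "cif"):
            cif_file = _pdbx.CIFFile.read(str(path))
            stack = _pdbx.get_structure(cif_file, model=None, altloc="occupancy")
        else:
            raise FormatError(f"unknown format {format!r}")
    except FormatError:
        raise
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        msg = str(exc)
        if "model" in msg.lower() and ("atom" in msg.lower() or "count" in msg.lower()):
            raise StructuralInconsistencyError(
                f"{path.name}: models differ in atom content ({msg})"
            ) from exc
        raise FormatError(f"{path.name}: could not parse as {fmt}: {msg}") from exc
    if exclude_hetero:
        stack = stack[..., ~stack.hetero]
    if stack.array_length() == 0:
        raise FormatError(f"{path.name}: no atoms after filtering")
    return TrajectoryFrames.from_biotite(stack)


def write_structure(frames: TrajectoryFrames, path: str | Path) -> None:
    """Write frames as a multi-model PDB file (one MODEL per frame)."""
    pdb_file = _pdb.PDBFile()
    _pdb.set_structure(pdb_file, frames.to_biotite())
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Selection and validation
# ---------------------------------------------------------------------------

def _mode_mask(frames: TrajectoryFrames, atom_mode: str) -> np.ndarray:
    heavy = ~np.isin(frames.element, ("H", "D"))
    if atom_mode == "CA_ONLY":
        return frames.atom_name == "CA"
    if atom_mode == "HEAVY":
        return heavy
    if atom_mode == "SIDE_CHAIN":
        return heavy & ~np.isin(frames.atom_name, tuple(BACKBONE_ATOMS))
    raise ValueError(f"unknown atom_mode {atom_mode!r}")


def select_segment(frames: TrajectoryFrames, seg: SegmentDefinition) -> np.ndarray:
    """Resolve a segment definition to atom indices (ascending atom_id).

    Raises :class:`EmptySelectionError` when nothing matches — most often an
    absent chain or a residue-numbering mismatch.
    """
    mask = frames.chain_id == seg.chain_id
    in_range = np.zeros(frames.n_atoms, dtype=bool)
    for a, b in seg.residue_ranges:
        in_range |= (frames.res_id >= a) & (frames.res_id <= b)
    mask &= in_range & _mode_mask(frames, seg.atom_mode)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise EmptySelectionError(
            f"segment {seg.label!r}: no atoms match chain {seg.chain_id!r}, "
            f"ranges {list(seg.residue_ranges)}, mode {seg.atom_mode}"
        )
    return idx[np.argsort(frames.atom_id[idx], kind="stable")]


@dataclass(frozen=True)
class ValidationEntry:
    label: str
    n_expected: int
    n_resolved: int
    missing: tuple[int, ...]
    flagged: bool

    @property
    def resolved_fraction(self) -> float:
        return self.n_resolved / self.n_expected if self.n_expected else 0.0


@dataclass
class ValidationReport:
    entries: list[ValidationEntry] = field(default_factory=list)
    min_fraction: float = 0.8

    @property
    def ok(self) -> bool:
        return not any(e.flagged for e in self.entries)


def validate_library(
    frames: TrajectoryFrames,
    lib: SegmentLibrary,
    min_fraction: float = 0.8,
) -> ValidationReport:
    """Report, per library entry, how many of its residues resolve.

    Classification downstream refuses to run when any required entry
    resolves fewer than ``min_fraction`` of its residues.
    """
    report = ValidationReport(min_fraction=min_fraction)
    for seg in lib:
        wanted = seg.residue_numbers
        on_chain = frames.res_id[frames.chain_id == seg.chain_id]
        present = set(int(r) for r in np.unique(on_chain))
        missing = tuple(r for r in wanted if r not in present)
        n_res = len(wanted) - len(missing)
        frac = n_res / len(wanted) if wanted else 0.0
        report.entries.append(
            ValidationEntry(
                label=seg.label,
                n_expected=len(wanted),
                n_resolved=n_res,
                missing=missing,
                flagged=frac < min_fraction,
            )
        )
    return report
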