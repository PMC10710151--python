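"""Per-frame residue-interaction detection and occurrence matrices.

For a focal residue (e.g. the Arg212 position of the GB2 subunit), every
frame is scanned for side-chain contacts with all other residues and each
focal–partner pair is classified as a salt bridge, hydrogen bond or generic
contact, in that priority order.  Stacking the per-frame presence of each
partner yields an occurrence matrix — rows are partner residues, columns
are frames — whose row means are interaction occupancies.

Detection criteria are geometric and configurable:

* SALT_BRIDGE — any atom of an oppositely charged side-chain group pair
  within ``saltbridge_max_dist`` (default 4.0 Å).
* HBOND — donor–acceptor heavy-atom distance ≤ ``hbond_max_dist``
  (default 3.5 Å); when the donor carries resolved hydrogens the
  donor–H–acceptor angle must additionally be ≥ ``hbond_min_angle``
  (default 120°).  Hydrogen-free structures fall back to distance-only
  detection, flagged on the matrix.
* CONTACT — any heavy-atom pair within ``contact_max_dist`` (default 4.5 Å).

``scope`` restricts which atoms may participate: SIDE_CHAIN (default,
matching side-chain-to-side-chain occurrence profiling) or ANY, which also
admits backbone atoms (and is the only way a glycine can partner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import LookupError_, ParameterError
from .structures import BACKBONE_ATOMS, TrajectoryFrames

__all__ = [
    "InteractionCriteria",
    "InteractionRecord",
    "OccurrenceMatrix",
    "detect_frame_interactions",
    "build_occurrence_matrix",
    "intersubunit_summary",
]

# Side-chain chemistry tables (standard amino-acid atom nomenclature).
POSITIVE_GROUP = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
NEGATIVE_GROUP = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
    "CYS": ("SG",),
}
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
}
BACKBONE_DONORS = ("N",)
BACKBONE_ACCEPTORS = ("O", "OXT")

BOND_PRIORITY = {"SALT_BRIDGE": 0, "HBOND": 1, "CONTACT": 2}


@dataclass(frozen=True)
class InteractionCriteria:
    hbond_max_dist: float = 3.5  # Å, donor–acceptor heavy atoms
    hbond_min_angle: float = 120.0  # degrees, donor–H–acceptor
    saltbridge_max_dist: float = 4.0  # Å
    contact_max_dist: float = 4.5  # Å
    scope: str = "SIDE_CHAIN"  # or "ANY"

    def __post_init__(self) -> None:
        if min(self.hbond_max_dist, self.saltbridge_max_dist, self.contact_max_dist) <= 0:
            raise ParameterError("all cutoff distances must be > 0")
        if not (0 < self.hbond_min_angle <= 180):
            raise ParameterError("hbond_min_angle must be in (0, 180]")
        if self.scope not in ("SIDE_CHAIN", "ANY"):
            raise ParameterError("scope must be SIDE_CHAIN or ANY")


@dataclass(frozen=True)
class InteractionRecord:
    frame: int
    focal: tuple[str, int]  # (chain_id, residue_number)
    partner: tuple[str, int]
    bond_type: str  # SALT_BRIDGE | HBOND | CONTACT
    distance: float  # Å


@dataclass
class OccurrenceMatrix:
    """Partner × frame interaction presence for one focal residue."""

    focal: tuple[str, int]
    partners: list[tuple[str, int]]
    presence: np.ndarray  # (n_partners, n_frames) bool
    occupancy: np.ndarray  # (n_partners,) in [0, 1]
    partner_subunit: list[str]  # per partner, "GB1" | "GB2" | "?"
    bond_types: list[set] = field(default_factory=list)  # types seen per partner
    hydrogen_free: bool = False  # distance-only H-bond fallback used

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            header = ["partner", "subunit", "occupancy"] + [
                f"f{t}" for t in range(self.presence.shape[1])
            ]
            fh.write("\t".join(header) + "\n")
            for i, p in enumerate(self.partners):
                row = [f"{p[0]}:{p[1]}", self.partner_subunit[i], f"{self.occupancy[i]:.4f}"]
                row += ["1" if v else "0" for v in self.presence[i]]
                fh.write("\t".join(row) + "\n")

    def summary(self) -> dict:
        return {
            "focal": list(self.focal),
            "n_frames": int(self.presence.shape[1]) if self.presence.size else 0,
            "partners": [
                {
                    "partner": list(p),
                    "subunit": self.partner_subunit[i],
                    "occupancy": float(self.occupancy[i]),
                    "bond_types": sorted(self.bond_types[i]) if self.bond_types else [],
                }
                for i, p in enumerate(self.partners)
            ],
            "hydrogen_free": self.hydrogen_free,
        }


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _residue_atom_indices(frames: TrajectoryFrames) -> dict[tuple[str, int], np.ndarray]:
    out: dict[tuple[str, int], list[int]] = {}
    for i in range(frames.n_atoms):
        out.setdefault((str(frames.chain_id[i]), int(frames.res_id[i])), []).append(i)
    return {k: np.array(v, dtype=int) for k, v in out.items()}


def _is_hydrogen(frames: TrajectoryFrames, i: int) -> bool:
    return frames.element[i] in ("H", "D")


def _scope_atoms(frames: TrajectoryFrames, indices: np.ndarray, scope: str) -> np.ndarray:
    """Heavy atoms eligible under the scope rule."""
    keep = []
    for i in indices:
        if _is_hydrogen(frames, i):
            continue
        if scope == "SIDE_CHAIN" and frames.atom_name[i] in BACKBONE_ATOMS:
            continue
        keep.append(i)
    return np.array(keep, dtype=int)


def _named_atoms(
    frames: TrajectoryFrames, indices: np.ndarray, names: Sequence[str]
) -> np.ndarray:
    return np.array([i for i in indices if frames.atom_name[i] in names], dtype=int)


def _attached_hydrogens(
    frames: TrajectoryFrames, frame: int, res_indices: np.ndarray, donor: int
) -> list[int]:
    """Hydrogens of the same residue within covalent range of the donor."""
    d_xyz = frames.coords[frame, donor]
    out = []
    for i in res_indices:
        if _is_hydrogen(frames, i) and np.linalg.norm(frames.coords[frame, i] - d_xyz) < 1.3:
            out.append(int(i))
    return out


def _donor_acceptor_names(res_name: str, scope: str, role: str) -> tuple[str, ...]:
    table = SIDECHAIN_DONORS if role == "donor" else SIDECHAIN_ACCEPTORS
    names = table.get(res_name, ())
    if scope == "ANY":
        names = names + (BACKBONE_DONORS if role == "donor" else BACKBONE_ACCEPTORS)
    return names


def _min_pair_distance(coords: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    if idx_a.size == 0 or idx_b.size == 0:
        return np.inf
    diff = coords[idx_a][:, None, :] - coords[idx_b][None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).min())


def residue_has_hydrogens(frames: TrajectoryFrames) -> bool:
    return bool(np.isin(frames.element, ("H", "D")).any())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def detect_frame_interactions(
    frames: TrajectoryFrames,
    frame: int,
    focal: tuple[str, int],
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[InteractionRecord]:
    """Classify interactions of the focal residue with every other residue.

    Each focal–partner pair yields at most one record, carrying the
    highest-priority bond type it satisfies (SALT_BRIDGE > HBOND > CONTACT)
    and the minimum distance that met that type's cutoff.
    """
    residues = _residue_atom_indices(frames)
    if focal not in residues:
        raise LookupError_(f"focal residue {focal} not present in structure")
    coords = frames.coords[frame]
    f_idx = residues[focal]
    f_name = str(frames.res_name[f_idx[0]])
    f_scope = _scope_atoms(frames, f_idx, criteria.scope)
    have_h = residue_has_hydrogens(frames)

    records: list[InteractionRecord] = []
    max_cut = max(criteria.hbond_max_dist, criteria.saltbridge_max_dist, criteria.contact_max_dist)
    for partner, p_idx in residues.items():
        if partner == focal:
            continue
        p_name = str(frames.res_name[p_idx[0]])
        p_scope = _scope_atoms(frames, p_idx, criteria.scope)
        if f_scope.size == 0 or p_scope.size == 0:
            continue
        # cheap rejection on scope-atom minimum distance
        d_scope = _min_pair_distance(coords, f_scope, p_scope)
        if d_scope > max_cut:
            continue

        best: tuple[str, float] | None = None

        # salt bridge: oppositely charged side-chain groups
        for pos_res, neg_res, pos_idx, neg_idx in (
            (f_name, p_name, f_idx, p_idx),
            (p_name, f_name, p_idx, f_idx),
        ):
            pos_atoms = _named_atoms(frames, pos_idx, POSITIVE_GROUP.get(pos_res, ()))
            neg_atoms = _named_atoms(frames, neg_idx, NEGATIVE_GROUP.get(neg_res, ()))
            d = _min_pair_distance(coords, pos_atoms, neg_atoms)
            if d <= criteria.saltbridge_max_dist:
                if best is None or d < best[1]:
                    best = ("SALT_BRIDGE", d)

        # hydrogen bond: donor/acceptor in either direction
        if best is None or best[0] != "SALT_BRIDGE":
            hb = _best_hbond(frames, frame, criteria, f_idx, f_name, p_idx, p_name, have_h)
            if hb is not None:
                best = ("HBOND", hb)

        # generic contact
        if best is None:
            d = _min_pair_distance(coords, f_scope, p_scope)
            if d <= criteria.contact_max_dist:
                best = ("CONTACT", d)

        if best is not None:
            records.append(
                InteractionRecord(
                    frame=frame, focal=focal, partner=partner,
                    bond_type=best[0], distance=best[1],
                )
            )
    return records


def _best_hbond(frames, frame, criteria, f_idx, f_name, p_idx, p_name, have_h):
    coords = frames.coords[frame]
    best = None
    for don_idx, don_name, acc_idx, acc_name in (
        (f_idx, f_name, p_idx, p_name),
        (p_idx, p_name, f_idx, f_name),
    ):
        donors = _named_atoms(
            frames, don_idx, _donor_acceptor_names(don_name, criteria.scope, "donor")
        )
        acceptors = _named_atoms(
            frames, acc_idx, _donor_acceptor_names(acc_name, criteria.scope, "acceptor")
        )
        for d in donors:
            hyds = _attached_hydrogens(frames, frame, don_idx, d) if have_h else []
            for a in acceptors:
                dist = float(np.linalg.norm(coords[d] - coords[a]))
                if dist > criteria.hbond_max_dist:
                    continue
                if hyds:
                    ok = False
                    for h in hyds:
                        v1 = coords[d] - coords[h]
                        v2 = coords[a] - coords[h]
                        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                        if angle >= criteria.hbond_min_angle:
                            ok = True
                            break
                    if not ok:
                        continue
                if best is None or dist < best:
                    best = dist
    return best


def build_occurrence_matrix(
    frames: TrajectoryFrames,
    focal: tuple[str, int],
    criteria: InteractionCriteria = InteractionCriteria(),
    chain_roles: Mapping[str, str] | None = None,
) -> OccurrenceMatrix:
    """Occurrence matrix of the focal residue over all frames.

    ``chain_roles`` maps chain ids to subunit roles ("GB1"/"GB2") for the
    inter-subunit summary; unmapped chains report "?".
    """
    chain_roles = dict(chain_roles or {})
    per_frame: list[list[InteractionRecord]] = [
        detect_frame_interactions(frames, t, focal, criteria) for t in range(frames.n_frames)
    ]
    partner_set: dict[tuple[str, int], set] = {}
    for recs in per_frame:
        for r in recs:
            partner_set.setdefault(r.partner, set()).add(r.bond_type)
    partners = sorted(partner_set)
    index = {p: i for i, p in enumerate(partners)}
    presence = np.zeros((len(partners), frames.n_frames), dtype=bool)
    for t, recs in enumerate(per_frame):
        for r in recs:
            presence[index[r.partner], t] = True
    occupancy = presence.mean(axis=1) if partners else np.zeros(0)
    order = np.argsort(-occupancy, kind="stable")
    partners = [partners[i] for i in order]
    presence = presence[order]
    occupancy = occupancy[order]
    return OccurrenceMatrix(
        focal=focal,
        partners=partners,
        presence=presence,
        occupancy=occupancy,
        partner_subunit=[chain_roles.get(p[0], "?") for p in partners],
        bond_types=[partner_set[p] for p in partners],
        hydrogen_free=not residue_has_hydrogens(frames),
    )


def intersubunit_summary(matrix: OccurrenceMatrix, threshold: float = 0.1) -> dict:
    """Partner counts per subunit among partners at or above an occupancy threshold."""
    gb1 = gb2 = 0
    max_cross = 0.0
    for i, p in enumerate(matrix.partners):
        if matrix.occupancy[i] < threshold:
            continue
        role = matrix.partner_subunit[i]
        if role == "GB1":
            gb1 += 1
        elif role == "GB2":
            gb2 += 1
    # max occupancy among partners on any chain different from the focal chain
    for i, p in enumerate(matrix.partners):
        if p[0] != matrix.focal[0] and matrix.occupancy[i] >= threshold:
            max_cross = max(max_cross, float(matrix.occupancy[i]))
    return {
        "gb1_partners": gb1,
        "gb2_partners": gb2,
        "max_cross_subunit_occupancy": max_cross,
        "threshold": threshold,
    }
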