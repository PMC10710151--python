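"""Synthetic trajectories and concentration–response data.

Every downstream stage of the package is testable without external
downloads because this module generates inputs with known ground truth:

* **Trajectories** — idealized poly-alanine segments (α-helical Cα traces
  with minimal N/C/O/CB decoration) placed so that named segment pairs have
  exact target COM separations, then perturbed per frame by rigid-body
  isotropic Gaussian jitter and optional linear drift.  Because jitter
  moves whole segments, the per-frame pair separation has an analytically
  known sampling distribution (mean = target), and the generator records
  the realized separations as bookkeeping ground truth.
* **Concentration–response curves** — replicates drawn from the
  three-parameter log-logistic model with i.i.d. Gaussian noise, at the
  packaged parameter sets of the functional characterization (basal, Emax,
  EC50 for the WT and the two Arg212 variants) plus a zero-concentration
  basal well per replicate.
* **Scripted interactions** — a focal arginine with partner glutamates
  switched inside/outside the salt-bridge cutoff frame by frame, so the
  occurrence matrix of the generated trajectory equals the script exactly.

All generators are pure functions of (profile, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConstraintError, ParameterError
from .pharm import ConcentrationResponse, logistic3
from .structures import SegmentDefinition, SegmentLibrary, TrajectoryFrames

__all__ = [
    "SegmentSpec",
    "TrajectoryProfile",
    "CurveProfile",
    "SyntheticTrajectory",
    "PartnerScript",
    "ScriptedInteractions",
    "generate_trajectory",
    "generate_curves",
    "generate_interaction_script",
    "trajectory_profile",
    "curve_profile",
    "TRAJECTORY_PROFILE_NAMES",
    "CURVE_PROFILE_NAMES",
]


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """Geometry spec of one synthetic segment (label + residue layout)."""

    label: str
    subunit_role: str
    chain_id: str
    residue_ranges: tuple[tuple[int, int], ...]

    @property
    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.residue_ranges)

    def to_definition(self, atom_mode: str = "CA_ONLY") -> SegmentDefinition:
        return SegmentDefinition(
            label=self.label,
            subunit_role=self.subunit_role,
            chain_id=self.chain_id,
            residue_ranges=self.residue_ranges,
            atom_mode=atom_mode,
        )


@dataclass(frozen=True)
class TrajectoryProfile:
    name: str
    segments: tuple[SegmentSpec, ...]
    pair_targets: Mapping[tuple[str, str], float]  # Å
    jitter_sd: float = 0.5  # Å, rigid-body per segment per frame
    drift_per_frame: float = 0.0  # Å of separation change per frame (2-seg pairs)
    n_frames: int = 250
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")
        for pair, d in self.pair_targets.items():
            if d <= 0:
                raise ParameterError(f"pair target {pair} must be > 0")


@dataclass(frozen=True)
class CurveProfile:
    name: str
    basal: float
    top: float
    ec50_uM: float
    noise_sd: float = 0.02
    concentrations_uM: tuple[float, ...] = tuple(np.logspace(-2, 2, 8))
    n_replicates: int = 15
    seed: int = 42

    def __post_init__(self) -> None:
        if self.ec50_uM <= 0:
            raise ParameterError("ec50_uM must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def log_ec50(self) -> float:
        """log10 of the EC50 in molar."""
        return float(np.log10(self.ec50_uM * 1e-6))


# Lobe and helix residue layouts mirror the packaged segment library
# (author numbering of the deposited heterodimer structures).
_LBUPPER = SegmentSpec("GB1_LBupper", "GB1", "A", ((222, 235), (247, 260)))
_LBLOWER = SegmentSpec("GB1_LBlower", "GB1", "A", ((347, 358), (368, 382)))
_TM = {
    "GB1_TM4": SegmentSpec("GB1_TM4", "GB1", "A", ((711, 731),)),
    "GB2_TM4": SegmentSpec("GB2_TM4", "GB2", "B", ((598, 618),)),
    "GB1_TM5": SegmentSpec("GB1_TM5", "GB1", "A", ((769, 789),)),
    "GB2_TM5": SegmentSpec("GB2_TM5", "GB2", "B", ((655, 675),)),
    "GB1_TM6": SegmentSpec("GB1_TM6", "GB1", "A", ((805, 825),)),
    "GB2_TM6": SegmentSpec("GB2_TM6", "GB2", "B", ((692, 712),)),
}

_VFTD_PAIR = ("GB1_LBupper", "GB1_LBlower")


def _vftd_profile(name: str, target: float) -> TrajectoryProfile:
    return TrajectoryProfile(
        name=name,
        segments=(_LBUPPER, _LBLOWER),
        pair_targets={_VFTD_PAIR: target},
        jitter_sd=0.5,
        n_frames=250,
        seed=42,
    )


def _tm_profile(name: str, tm6: float, tm5: float, tm4: float) -> TrajectoryProfile:
    return TrajectoryProfile(
        name=name,
        segments=tuple(_TM.values()),
        pair_targets={
            ("GB1_TM6", "GB2_TM6"): tm6,
            ("GB1_TM5", "GB2_TM5"): tm5,
            ("GB1_TM4", "GB2_TM4"): tm4,
        },
        jitter_sd=0.5,
        n_frames=100,
        seed=42,
    )


# VFTD targets: midpoints of the simulated ranges (inactive WT 41–42 Å →
# 41.5; active 34–35 Å → 34.5) and the variant point values.  TM baselines
# are illustrative plausible helix separations; only the direction of each
# variant shift is established, encoded here as ±2 Å effects.
_TRAJECTORY_PROFILES = {
    "WT-inactive-VFTD": lambda: _vftd_profile("WT-inactive-VFTD", 41.5),
    "active-VFTD": lambda: _vftd_profile("active-VFTD", 34.5),
    "R212Q-inactive-VFTD": lambda: _vftd_profile("R212Q-inactive-VFTD", 37.5),
    "R212W-inactive-VFTD": lambda: _vftd_profile("R212W-inactive-VFTD", 34.5),
    "WT-TM": lambda: _tm_profile("WT-TM", tm6=32.0, tm5=30.0, tm4=28.0),
    "R212Q-TM": lambda: _tm_profile("R212Q-TM", tm6=30.0, tm5=32.0, tm4=30.0),
    "R212W-TM": lambda: _tm_profile("R212W-TM", tm6=34.0, tm5=28.0, tm4=28.0),
}
TRAJECTORY_PROFILE_NAMES = tuple(_TRAJECTORY_PROFILES)

# Functional-characterization parameter sets (basal, Emax, EC50 μM); the
# two WT sets belong to separate experiment batches and are kept separate.
_CURVE_PROFILES = {
    "WT-Q": (0.08, 1.02, 1.58, 15),
    "R212Q": (0.26, 0.86, 0.49, 15),
    "WT-W": (0.06, 1.04, 1.51, 8),
    "R212W": (-0.02, 1.06, 4.18, 8),
}
CURVE_PROFILE_NAMES = tuple(_CURVE_PROFILES)


def trajectory_profile(name: str, **overrides) -> TrajectoryProfile:
    """A packaged trajectory profile, optionally with fields overridden."""
    if name not in _TRAJECTORY_PROFILES:
        raise ParameterError(f"unknown trajectory profile {name!r}; have {TRAJECTORY_PROFILE_NAMES}")
    prof = _TRAJECTORY_PROFILES[name]()
    return replace(prof, **overrides) if overrides else prof


def curve_profile(name: str, **overrides) -> CurveProfile:
    """A packaged concentration–response profile."""
    if name not in _CURVE_PROFILES:
        raise ParameterError(f"unknown curve profile {name!r}; have {CURVE_PROFILE_NAMES}")
    basal, top, ec50, n_rep = _CURVE_PROFILES[name]
    prof = CurveProfile(name=name, basal=basal, top=top, ec50_uM=ec50, n_replicates=n_rep)
    return replace(prof, **overrides) if overrides else prof


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

_ATOM_NAMES = ("N", "CA", "C", "O", "CB")
_ELEMENTS = ("N", "C", "C", "O", "C")
# local offsets from Cα, Å — coarse poly-alanine decoration
_OFFSETS = {
    "N": np.array([-1.20, 0.60, -0.50]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.20, 0.60, 0.50]),
    "O": np.array([1.60, 1.70, 0.55]),
    "CB": np.array([-0.30, -1.40, 0.40]),
}


def _helix_ca(n: int) -> np.ndarray:
    """Ideal α-helix Cα trace: 2.3 Å radius, 1.5 Å rise, 100°/residue."""
    t = np.arange(n)
    ang = np.deg2rad(100.0 * t)
    return np.column_stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * t])


def _build_segment_template(spec: SegmentSpec) -> tuple[np.ndarray, dict]:
    """Atoms of one segment, Cα centroid at the origin."""
    n = spec.n_residues
    ca = _helix_ca(n)
    ca -= ca.mean(axis=0)  # CA_ONLY centre of mass exactly at origin
    res_numbers = []
    for a, b in spec.residue_ranges:
        res_numbers.extend(range(a, b + 1))
    coords, names, elements, res_ids = [], [], [], []
    for i, resnum in enumerate(res_numbers):
        for name, element in zip(_ATOM_NAMES, _ELEMENTS):
            coords.append(ca[i] + _OFFSETS[name])
            names.append(name)
            elements.append(element)
            res_ids.append(resnum)
    meta = {
        "atom_name": np.array(names),
        "element": np.array(elements),
        "res_id": np.array(res_ids, dtype=int),
        "res_name": np.array(["ALA"] * len(names)),
        "chain_id": np.array([spec.chain_id] * len(names)),
    }
    return np.array(coords), meta


def _embed_component(
    labels: list[str], targets: Mapping[tuple[str, str], float]
) -> dict[str, np.ndarray]:
    """Base positions of one connected component of the pair graph."""
    k = len(labels)
    if k == 1:
        return {labels[0]: np.zeros(3)}
    lookup = {}
    for (a, b), d in targets.items():
        lookup[(a, b)] = d
        lookup[(b, a)] = d
    if k == 2:
        d = lookup[(labels[0], labels[1])]
        return {labels[0]: np.zeros(3), labels[1]: np.array([d, 0.0, 0.0])}
    # complete specification required for larger components
    dmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            key = (labels[i], labels[j])
            if key not in lookup:
                raise ConstraintError(
                    f"pair target missing for {key}; components of >2 segments "
                    "need all pairwise targets"
                )
            dmat[i, j] = dmat[j, i] = lookup[key]
    # classical MDS into 3 dimensions
    d2 = dmat**2
    j_mat = np.eye(k) - np.ones((k, k)) / k
    b_mat = -0.5 * j_mat @ d2 @ j_mat
    eigval, eigvec = np.linalg.eigh(b_mat)
    order = np.argsort(eigval)[::-1][:3]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    realized = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if not np.allclose(realized, dmat, atol=1e-6):
        raise ConstraintError(
            f"pair targets for {labels} are not embeddable in 3-D "
            "(triangle inequality or rank violation)"
        )
    return {label: coords[i] for i, label in enumerate(labels)}


def _components(labels: Sequence[str], pairs: Mapping[tuple[str, str], float]) -> list[list[str]]:
    adj: dict[str, set] = {l: set() for l in labels}
    for a, b in pairs:
        if a not in adj or b not in adj:
            raise ConstraintError(f"pair target references unknown segment in {(a, b)}")
        adj[a].add(b)
        adj[b].add(a)
    seen: set = set()
    comps = []
    for l in labels:
        if l in seen:
            continue
        stack, comp = [l], []
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            comp.append(cur)
            stack.extend(adj[cur] - seen)
        comps.append(sorted(comp))
    return comps


@dataclass
class SyntheticTrajectory:
    """Generated frames plus the library and bookkeeping ground truth."""

    frames: TrajectoryFrames
    library: SegmentLibrary
    realized_separations: dict[tuple[str, str], np.ndarray]  # per frame, Å
    profile: TrajectoryProfile

    def bookkeeping(self) -> dict:
        return {
            "profile": self.profile.name,
            "seed": self.profile.seed,
            "n_frames": self.profile.n_frames,
            "jitter_sd": self.profile.jitter_sd,
            "pairs": {
                "|".join(pair): {
                    "target_A": float(self.profile.pair_targets[pair]),
                    "realized_mean_A": float(np.mean(sep)),
                    "realized_sd_A": float(np.std(sep, ddof=1)),
                    "realized_A": [float(x) for x in sep],
                }
                for pair, sep in self.realized_separations.items()
            },
        }


def generate_trajectory(profile: TrajectoryProfile) -> SyntheticTrajectory:
    """Build a synthetic multi-segment trajectory with known separations.

    Segments are placed so that every pair's Cα-centroid separation equals
    its target; per frame each segment is rigidly displaced by isotropic
    Gaussian jitter and, for two-segment pairs, an optional linear drift
    that changes the separation by ``drift_per_frame`` per frame.
    Reproducible: identical profiles give bit-identical coordinates.
    """
    labels = [s.label for s in profile.segments]
    if len(set(labels)) != len(labels):
        raise ConstraintError("segment labels must be unique")
    comps = _components(labels, profile.pair_targets)
    base: dict[str, np.ndarray] = {}
    for ci, comp in enumerate(comps):
        local_targets = {
            p: d for p, d in profile.pair_targets.items() if p[0] in comp
        }
        placed = _embed_component(comp, local_targets)
        offset = np.array([400.0 * ci, 0.0, 0.0])
        for label, pos in placed.items():
            base[label] = pos + offset

    if profile.drift_per_frame != 0.0:
        for comp in comps:
            if len(comp) > 2:
                raise ConstraintError(
                    "linear drift is only defined for two-segment pairs"
                )

    rng = np.random.default_rng(profile.seed)
    n_seg = len(profile.segments)
    f = profile.n_frames
    jitter = (
        rng.normal(0.0, profile.jitter_sd, size=(f, n_seg, 3))
        if profile.jitter_sd > 0
        else np.zeros((f, n_seg, 3))
    )

    # drift: move the two members of each pair apart along their base axis
    drift = np.zeros((f, n_seg, 3))
    if profile.drift_per_frame != 0.0:
        t = np.arange(f)[:, None]
        seg_index = {l: i for i, l in enumerate(labels)}
        for (a, b) in profile.pair_targets:
            axis = base[b] - base[a]
            axis = axis / np.linalg.norm(axis)
            drift[:, seg_index[a], :] -= 0.5 * profile.drift_per_frame * t * axis
            drift[:, seg_index[b], :] += 0.5 * profile.drift_per_frame * t * axis

    # assemble atoms
    templates = [_build_segment_template(s) for s in profile.segments]
    meta_cat = {k: np.concatenate([m[k] for _, m in templates]) for k in templates[0][1]}
    atom_counts = [len(tpl) for tpl, _ in templates]
    n_atoms = sum(atom_counts)
    coords = np.empty((f, n_atoms, 3))
    centers = np.empty((f, n_seg, 3))
    start = 0
    for si, (tpl, _) in enumerate(templates):
        pos = base[labels[si]][None, :] + jitter[:, si, :] + drift[:, si, :]
        centers[:, si, :] = pos
        coords[:, start : start + atom_counts[si], :] = tpl[None, :, :] + pos[:, None, :]
        start += atom_counts[si]

    frames = TrajectoryFrames(
        atom_id=np.arange(n_atoms, dtype=int),
        atom_name=meta_cat["atom_name"],
        element=meta_cat["element"],
        chain_id=meta_cat["chain_id"],
        res_id=meta_cat["res_id"],
        res_name=meta_cat["res_name"],
        coords=coords,
    )
    library = SegmentLibrary(
        {s.label: s.to_definition() for s in profile.segments},
        provenance=f"synthetic profile {profile.name!r} (seed {profile.seed})",
    )
    seg_index = {l: i for i, l in enumerate(labels)}
    realized = {
        pair: np.linalg.norm(
            centers[:, seg_index[pair[0]], :] - centers[:, seg_index[pair[1]], :], axis=1
        )
        for pair in profile.pair_targets
    }
    return SyntheticTrajectory(frames, library, realized, profile)


# ---------------------------------------------------------------------------
# Concentration–response generation
# ---------------------------------------------------------------------------

def generate_curves(
    profile: CurveProfile,
    n_replicates: int | None = None,
    seed: int | None = None,
) -> list[ConcentrationResponse]:
    """Replicate curves from the three-parameter model plus Gaussian noise.

    Each replicate carries one zero-concentration basal well followed by
    the profile's concentration grid.  Deterministic under fixed seed.
    """
    n_rep = profile.n_replicates if n_replicates is None else n_replicates
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    conc_m = np.concatenate([[0.0], np.asarray(profile.concentrations_uM) * 1e-6])
    clean = logistic3(conc_m, profile.basal, profile.top, profile.log_ec50)
    out = []
    for rep in range(n_rep):
        noise = rng.normal(0.0, profile.noise_sd, size=clean.shape) if profile.noise_sd else 0.0
        out.append(
            ConcentrationResponse(
                label=profile.name,
                concentrations=conc_m,
                responses=clean + noise,
                replicate_id=rep,
            )
        )
    return out


def curves_to_dataframe(curves: Sequence[ConcentrationResponse]):
    """Flatten replicate curves into the CSV dialect of the pharm module."""
    import pandas as pd

    rows = []
    for c in curves:
        for conc, resp in zip(c.concentrations, c.responses):
            rows.append(
                {
                    "condition": c.label,
                    "replicate": c.replicate_id,
                    "concentration_M": conc,
                    "response": resp,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scripted interaction trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartnerScript:
    """On/off pattern of one partner residue across frames."""

    chain_id: str
    residue_number: int
    pattern: tuple[bool, ...]


@dataclass
class ScriptedInteractions:
    frames: TrajectoryFrames
    focal: tuple[str, int]
    partners: list[PartnerScript]
    chain_roles: dict[str, str]


# focal arginine side chain, extended along +x from CA at the origin
_ARG_ATOMS = {
    "N": ([-1.45, 0.50, 0.0], "N"),
    "CA": ([0.0, 0.0, 0.0], "C"),
    "C": ([1.30, 0.70, 0.0], "C"),
    "O": ([1.40, 1.95, 0.0], "O"),
    "CB": ([0.20, -1.52, 0.0], "C"),
    "CG": ([1.60, -2.10, 0.0], "C"),
    "CD": ([1.70, -3.62, 0.0], "C"),
    "NE": ([3.05, -4.18, 0.0], "N"),
    "CZ": ([3.30, -5.50, 0.0], "C"),
    "NH1": ([4.55, -5.95, 0.0], "N"),
    "NH2": ([2.35, -6.40, 0.0], "N"),
}

# glutamate partner, OE1 leading (placed nearest the focal guanidinium)
_GLU_ATOMS = {
    "OE1": ([0.0, 0.0, 0.0], "O"),
    "OE2": ([0.65, 2.05, 0.0], "O"),
    "CD": ([0.85, 0.85, 0.0], "C"),
    "CG": ([2.30, 0.45, 0.0], "C"),
    "CB": ([3.30, 1.60, 0.0], "C"),
    "CA": ([4.75, 1.15, 0.0], "C"),
    "N": ([5.70, 2.30, 0.0], "N"),
    "C": ([5.25, -0.05, 0.0], "C"),
    "O": ([6.40, -0.30, 0.0], "O"),
}

_ON_DISTANCE = 3.0  # Å, NH1–OE1 when a partner is scripted "on"
_OFF_DISTANCE = 25.0  # Å, safely beyond every cutoff


def generate_interaction_script(
    n_frames: int,
    partners: Sequence[PartnerScript],
    focal: tuple[str, int] = ("B", 212),
    chain_roles: Mapping[str, str] | None = None,
) -> ScriptedInteractions:
    """Trajectory whose occurrence matrix equals the script exactly.

    The focal residue is an arginine; each partner is a glutamate whose
    carboxylate is placed 3 Å from the focal guanidinium in "on" frames
    (a salt bridge under default criteria) and 25 Å away in "off" frames.
    Partners occupy distinct directions so their placements never conflict.
    """
    if not partners:
        raise ParameterError("need at least one partner script")
    for p in partners:
        if len(p.pattern) != n_frames:
            raise ConstraintError(
                f"partner {p.chain_id}:{p.residue_number} pattern length "
                f"{len(p.pattern)} != n_frames {n_frames}"
            )
    keys = {(p.chain_id, p.residue_number) for p in partners}
    if len(keys) != len(partners) or focal in keys:
        raise ConstraintError("partner identities must be unique and differ from focal")

    chain_roles = dict(chain_roles or {"A": "GB1", "B": "GB2"})
    nh1 = np.array(_ARG_ATOMS["NH1"][0])

    names, elements, chains, res_ids, res_names = [], [], [], [], []
    for name, (xyz, el) in _ARG_ATOMS.items():
        names.append(name)
        elements.append(el)
        chains.append(focal[0])
        res_ids.append(focal[1])
        res_names.append("ARG")

    # one well-separated direction per partner, fanning out from NH1
    k = len(partners)
    phis = 2.0 * np.pi * np.arange(k) / max(k, 1)
    directions = np.column_stack(
        [np.full(k, 1.0), 0.8 * np.cos(phis), 0.8 * np.sin(phis)]
    )
    directions /= np.linalg.norm(directions, axis=1)[:, None]

    partner_atoms = []  # (base local coords rotated? keep axis-aligned offsets)
    for pi, p in enumerate(partners):
        for name, (xyz, el) in _GLU_ATOMS.items():
            names.append(name)
            elements.append(el)
            chains.append(p.chain_id)
            res_ids.append(p.residue_number)
            res_names.append("GLU")
        partner_atoms.append(np.array([xyz for xyz, _ in _GLU_ATOMS.values()]))

    n_focal = len(_ARG_ATOMS)
    n_per_partner = len(_GLU_ATOMS)
    n_atoms = n_focal + k * n_per_partner
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, :n_focal, :] = np.array([xyz for xyz, _ in _ARG_ATOMS.values()])[None]
    for pi, p in enumerate(partners):
        d = directions[pi]
        # local frame: x-axis pointing away from the focal residue
        x_axis = d
        helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        y_axis = np.cross(helper, x_axis)
        y_axis /= np.linalg.norm(y_axis)
        z_axis = np.cross(x_axis, y_axis)
        rot = np.column_stack([x_axis, y_axis, z_axis])
        local = partner_atoms[pi] @ rot.T
        a0 = n_focal + pi * n_per_partner
        for t in range(n_frames):
            anchor = nh1 + (_ON_DISTANCE if p.pattern[t] else _OFF_DISTANCE) * d
            coords[t, a0 : a0 + n_per_partner, :] = local + anchor

    frames = TrajectoryFrames(
        atom_id=np.arange(n_atoms, dtype=int),
        atom_name=np.array(names),
        element=np.array(elements),
        chain_id=np.array(chains),
        res_id=np.array(res_ids, dtype=int),
        res_name=np.array(res_names),
        coords=coords,
    )
    return ScriptedInteractions(
        frames=frames, focal=focal, partners=list(partners), chain_roles=chain_roles
    )
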