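"""End-to-end orchestration: profile distances, classify, fit pharmacology.

The pipeline stages mirror the analysis workflow: generate or load WT and
variant trajectories, profile the configured segment-pair distances (VFTD
lobes, TM4/TM5/TM6), compare them and emit a gain/loss-of-function call,
and fit concentration–response tables.  Every output embeds the hash of
the configuration that produced it, so equal hashes plus equal seeds imply
equal numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .classify import (
    DistanceShift,
    ReferenceDistances,
    StateCall,
    VftdEvidence,
    classify_variant,
    compare_distance_series,
    vftd_closure_index,
)
from .errors import GpcrVarError, ParameterError
from .geometry import DEFAULT_SIGMA_FRAMES, DistanceSeries, com_distance_series
from .interactions import InteractionCriteria, build_occurrence_matrix, intersubunit_summary
from .pharm import fit_dose_response, read_curves_csv, summarize_groups, write_fits_csv
from .structures import (
    SegmentLibrary,
    TrajectoryFrames,
    default_library,
    load_structure,
    validate_library,
)

__all__ = ["PipelineConfig", "run_profile", "run_classify", "run_pharm", "run_simulate"]

#: Segment pairs profiled by default: lobes of the GB1 VFTD plus the three
#: inter-subunit TM helix pairs.
DEFAULT_PAIRS = (
    ("GB1_LBupper", "GB1_LBlower"),
    ("GB1_TM4", "GB2_TM4"),
    ("GB1_TM5", "GB2_TM5"),
    ("GB1_TM6", "GB2_TM6"),
)


@dataclass
class PipelineConfig:
    wt_structure: str
    var_structure: str
    chain_roles: dict = field(default_factory=lambda: {"GB1": "A", "GB2": "B"})
    segment_library: str | None = None  # path; packaged default when None
    pairs: tuple = DEFAULT_PAIRS
    sigma_frames: float = DEFAULT_SIGMA_FRAMES
    equilibration_fraction: float = 0.1
    min_effect_A: float = 1.0
    k_sd: float = 2.0
    min_resolved_fraction: float = 0.8
    interaction_criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    out_dir: str = "gpcrvar_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.equilibration_fraction < 1):
            raise ParameterError("equilibration_fraction must be in [0, 1)")
        if self.sigma_frames < 0 or self.min_effect_A < 0 or self.k_sd < 0:
            raise ParameterError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        crit = doc.pop("interaction_criteria", None)
        cfg = cls(**doc)
        if crit:
            cfg.interaction_criteria = InteractionCriteria(**crit)
        return cfg

    def digest(self) -> str:
        doc = asdict(self)
        doc["pairs"] = [list(p) for p in self.pairs]
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _library_for(config: PipelineConfig) -> SegmentLibrary:
    lib = (
        SegmentLibrary.from_yaml(config.segment_library)
        if config.segment_library
        else default_library()
    )
    return lib.with_chain_roles(config.chain_roles)


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.digest(), "version": __version__, "seed": config.seed}


def _profile_condition(
    frames: TrajectoryFrames,
    lib: SegmentLibrary,
    config: PipelineConfig,
) -> dict[tuple[str, str], DistanceSeries]:
    report = validate_library(frames, lib, config.min_resolved_fraction)
    needed = {label for pair in config.pairs for label in pair}
    bad = [e.label for e in report.entries if e.label in needed and e.flagged]
    if bad:
        raise GpcrVarError(
            f"segments {bad} resolve fewer than "
            f"{config.min_resolved_fraction:.0%} of their residues; refusing to run"
        )
    out = {}
    for a, b in config.pairs:
        out[(str(a), str(b))] = com_distance_series(frames, lib[a], lib[b], config.sigma_frames)
    return out


def run_profile(config: PipelineConfig) -> dict:
    """Profile all configured pair distances for WT and variant structures.

    Writes one CSV (frame, raw, filtered) and one JSON summary per pair and
    condition under ``out_dir``; returns the in-memory series.
    """
    lib = _library_for(config)
    # fail before writing anything if either structure is unreadable
    loaded = {
        "wt": load_structure(config.wt_structure),
        "var": load_structure(config.var_structure),
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    for condition, frames in loaded.items():
        series = _profile_condition(frames, lib, config)
        results[condition] = series
        for (a, b), ds in series.items():
            stem = f"{condition}_{a}__{b}"
            ds.to_csv(out_dir / f"{stem}.csv")
            doc = ds.summary() | _provenance(config)
            (out_dir / f"{stem}.json").write_text(json.dumps(doc, indent=2))
    return results


def run_classify(config: PipelineConfig) -> StateCall:
    """Profile WT and variant, compare pairs, and emit the StateCall report."""
    series = run_profile(config)
    tm_shifts: list[DistanceShift] = []
    vftd_evidence: VftdEvidence | None = None
    refs = ReferenceDistances()
    for pair in config.pairs:
        pair = (str(pair[0]), str(pair[1]))
        wt = series["wt"][pair]
        var = series["var"][pair]
        shift = compare_distance_series(
            wt, var, config.min_effect_A, config.k_sd, config.equilibration_fraction
        )
        if "TM" in pair[0].upper():
            tm_shifts.append(shift)
        elif "LB" in pair[0].upper():
            vftd_evidence = VftdEvidence(
                shift=shift,
                closure_index_wt=vftd_closure_index(wt, refs),
                closure_index_var=vftd_closure_index(var, refs),
            )
    call = classify_variant(tm_shifts, vftd_evidence, refs)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    call.to_json(out_dir / "state_call.json", extra=_provenance(config))
    return call


def run_interactions(
    config: PipelineConfig,
    structure: str,
    focal: tuple[str, int],
) -> dict:
    """Occurrence matrix + inter-subunit summary for one focal residue."""
    frames = load_structure(structure)
    roles = {chain: role for role, chain in config.chain_roles.items()}
    matrix = build_occurrence_matrix(frames, focal, config.interaction_criteria, roles)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"interactions_{focal[0]}_{focal[1]}"
    matrix.to_tsv(out_dir / f"{stem}.tsv")
    summary = {
        "matrix": matrix.summary(),
        "intersubunit": intersubunit_summary(matrix),
    } | _provenance(config)
    (out_dir / f"{stem}.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_pharm(csv_path: str | Path, out_dir: str | Path, config: PipelineConfig | None = None) -> dict:
    """Fit every replicate in a concentration–response CSV and summarize."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves = read_curves_csv(csv_path)
    fits = [fit_dose_response(c) for c in curves]
    write_fits_csv(fits, out_dir / "fits.csv")
    by_condition: dict[str, list] = {}
    for fit in fits:
        by_condition.setdefault(fit.label, []).append(fit)
    summary = summarize_groups(by_condition)
    doc = {"groups": summary.to_dict(orient="records")}
    if config is not None:
        doc |= _provenance(config)
    (out_dir / "group_summary.json").write_text(json.dumps(doc, indent=2))
    return doc


def run_simulate(profile_name: str, out_dir: str | Path, seed: int | None = None) -> Path:
    """Materialize a packaged synthetic profile to disk.

    Trajectory profiles are written as a multi-model PDB plus a JSON
    bookkeeping file of realized separations; curve profiles as the
    pharmacology CSV dialect.
    """
    from . import synthetic
    from .structures import write_structure

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if profile_name in synthetic.TRAJECTORY_PROFILE_NAMES:
        kwargs = {"seed": seed} if seed is not None else {}
        traj = synthetic.generate_trajectory(synthetic.trajectory_profile(profile_name, **kwargs))
        pdb_path = out_dir / f"{profile_name}.pdb"
        write_structure(traj.frames, pdb_path)
        (out_dir / f"{profile_name}.bookkeeping.json").write_text(
            json.dumps(traj.bookkeeping(), indent=2)
        )
        traj.library.to_yaml(out_dir / f"{profile_name}.segments.yaml")
        return pdb_path
    if profile_name in synthetic.CURVE_PROFILE_NAMES:
        prof = synthetic.curve_profile(profile_name, **({"seed": seed} if seed is not None else {}))
        curves = synthetic.generate_curves(prof)
        df = synthetic.curves_to_dataframe(curves)
        csv_path = out_dir / f"{profile_name}.curves.csv"
        df.to_csv(csv_path, index=False)
        return csv_path
    raise ParameterError(
        f"unknown profile {profile_name!r}; trajectories: "
        f"{synthetic.TRAJECTORY_PROFILE_NAMES}, curves: {synthetic.CURVE_PROFILE_NAMES}"
    )
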