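import numpy as np
import pytest

from gpcrvar.structures import TrajectoryFrames


def make_frames(records, coords):
    """Build TrajectoryFrames from (name, element, chain, resid, resname) rows.

    ``coords`` is (n_frames, n_atoms, 3) or (n_atoms, 3).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    return TrajectoryFrames(
        atom_id=np.arange(len(records)),
        atom_name=np.array([r[0] for r in records]),
        element=np.array([r[1] for r in records]),
        chain_id=np.array([r[2] for r in records]),
        res_id=np.array([r[3] for r in records], dtype=int),
        res_name=np.array([r[4] for r in records]),
        coords=coords,
    )


def toy_pdb_text(n_models=1, n_atoms=3, shift_per_model=1.0, drop_atom_in_model=None):
    """Minimal multi-model PDB text: ALA chain A with CA/N/C atoms."""
    names = ["N", "CA", "C", "O", "CB"]
    lines = []
    for m in range(n_models):
        lines.append(f"MODEL     {m + 1:4d}")
        serial = 1
        for a in range(n_atoms):
            if drop_atom_in_model == (m, a):
                continue
            name = names[a % len(names)]
            res = a // len(names) + 1
            x = float(a) + m * shift_per_model
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}ALA A{res:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           "
                f"{name[0]:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_pdb(tmp_path):
    def _write(text, name="toy.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
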