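import numpy as np
import pytest

from gpcrvar.errors import LookupError_, ParameterError
from gpcrvar.interactions import (
    BACKBONE_ATOMS,
    InteractionCriteria,
    NEGATIVE_GROUP,
    POSITIVE_GROUP,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    build_occurrence_matrix,
    detect_frame_interactions,
    intersubunit_summary,
)
from gpcrvar.synthetic import PartnerScript, generate_interaction_script

from conftest import make_frames


def _arg_glu_frame(gap=3.0):
    """Minimal Arg/Glu pair: NH1 and OE1 separated by ``gap`` Å."""
    records = [
        ("CB", "C", "A", 1, "ARG"),
        ("NH1", "N", "A", 1, "ARG"),
        ("CB", "C", "B", 2, "GLU"),
        ("OE1", "O", "B", 2, "GLU"),
    ]
    coords = [[-1.5, 0, 0], [0, 0, 0], [gap + 1.5, 0, 0], [gap, 0, 0]]
    return make_frames(records, coords)


class TestDetectFrameInteractions:
    def test_salt_bridge_detected(self):
        frames = _arg_glu_frame(gap=3.0)
        recs = detect_frame_interactions(frames, 0, ("A", 1))
        assert len(recs) == 1
        assert recs[0].bond_type == "SALT_BRIDGE"
        assert recs[0].distance == pytest.approx(3.0)
        assert recs[0].partner == ("B", 2)

    def test_beyond_cutoff_no_record(self):
        frames = _arg_glu_frame(gap=6.0)
        assert detect_frame_interactions(frames, 0, ("A", 1)) == []

    def test_backbone_acceptor_excluded_in_sidechain_scope(self):
        # Ser OG donor (with ideal H) 2.9 A from a backbone carbonyl O
        records = [
            ("OG", "O", "A", 1, "SER"),
            ("HG", "H", "A", 1, "SER"),
            ("O", "O", "B", 2, "ALA"),  # backbone acceptor
            ("CA", "C", "B", 2, "ALA"),
        ]
        coords = [[0, 0, 0], [0.96, 0, 0], [2.9, 0, 0], [4.4, 0, 0]]
        frames = make_frames(records, coords)
        side = detect_frame_interactions(
            frames, 0, ("A", 1), InteractionCriteria(scope="SIDE_CHAIN")
        )
        assert side == []
        any_scope = detect_frame_interactions(
            frames, 0, ("A", 1), InteractionCriteria(scope="ANY")
        )
        assert [r.bond_type for r in any_scope] == ["HBOND"]

    def test_hbond_angle_gate_with_hydrogens(self):
        # donor-H-acceptor at 90 degrees fails the default 120-degree gate
        records = [
            ("OG", "O", "A", 1, "SER"),
            ("HG", "H", "A", 1, "SER"),
            ("OE1", "O", "B", 2, "GLU"),
        ]
        coords = [[0, 0, 0], [0.96, 0, 0], [0.96, 2.0, 0]]
        frames = make_frames(records, coords)
        recs = detect_frame_interactions(frames, 0, ("A", 1))
        # the 2.2 Å O–O distance would be an H-bond by distance alone, but
        # the bent geometry demotes the pair to a generic contact
        assert [r.bond_type for r in recs] == ["CONTACT"]

    def test_missing_focal_residue(self):
        frames = _arg_glu_frame()
        with pytest.raises(LookupError_):
            detect_frame_interactions(frames, 0, ("Z", 99))

    def test_matches_exhaustive_pairwise_oracle(self):
        frames, focal = _random_small_frame(seed=21)
        criteria = InteractionCriteria()
        got = {
            (r.partner, r.bond_type)
            for r in detect_frame_interactions(frames, 0, focal, criteria)
        }
        assert got == _oracle_records(frames, focal, criteria)

    def test_detection_monotone_in_cutoffs(self):
        frames, focal = _random_small_frame(seed=8)
        tight = InteractionCriteria(
            hbond_max_dist=3.0, saltbridge_max_dist=3.5, contact_max_dist=4.0
        )
        loose = InteractionCriteria(
            hbond_max_dist=3.8, saltbridge_max_dist=4.5, contact_max_dist=5.5
        )
        tight_partners = {r.partner for r in detect_frame_interactions(frames, 0, focal, tight)}
        loose_partners = {r.partner for r in detect_frame_interactions(frames, 0, focal, loose)}
        assert tight_partners <= loose_partners


def _random_small_frame(seed, n_res=8):
    """A cluster of charged/polar residues for oracle comparison."""
    rng = np.random.default_rng(seed)
    templates = {
        "ARG": [("CB", "C"), ("NE", "N"), ("NH1", "N"), ("NH2", "N")],
        "GLU": [("CB", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")],
        "SER": [("CB", "C"), ("OG", "O")],
        "ASN": [("CB", "C"), ("OD1", "O"), ("ND2", "N")],
        "LYS": [("CB", "C"), ("NZ", "N")],
    }
    names = list(templates)
    records, coords = [], []
    for r in range(1, n_res + 1):
        res_name = names[(r - 1) % len(names)]
        chain = "A" if r % 2 else "B"
        center = rng.uniform(-4, 4, size=3)
        for atom, element in templates[res_name]:
            records.append((atom, element, chain, r, res_name))
            coords.append(center + rng.uniform(-1.0, 1.0, size=3))
    frames = make_frames(records, coords)
    return frames, ("A", 1)


def _oracle_records(frames, focal, criteria):
    """Independent exhaustive evaluation of all side-chain atom pairs."""
    out = set()
    coords = frames.coords[0]
    keys = [(str(c), int(r)) for c, r in zip(frames.chain_id, frames.res_id)]
    partners = sorted(set(keys) - {focal})
    for partner in partners:
        f_atoms = [i for i, k in enumerate(keys) if k == focal]
        p_atoms = [i for i, k in enumerate(keys) if k == partner]
        f_res = str(frames.res_name[f_atoms[0]])
        p_res = str(frames.res_name[p_atoms[0]])

        def side(idx):
            return [
                i for i in idx
                if frames.element[i] != "H" and frames.atom_name[i] not in BACKBONE_ATOMS
            ]

        fs, ps = side(f_atoms), side(p_atoms)
        dist = {
            (i, j): np.linalg.norm(coords[i] - coords[j]) for i in fs for j in ps
        }
        if not dist:
            continue
        salt = False
        for i in fs:
            for j in ps:
                fa, pa = str(frames.atom_name[i]), str(frames.atom_name[j])
                pos_neg = (
                    fa in POSITIVE_GROUP.get(f_res, ()) and pa in NEGATIVE_GROUP.get(p_res, ())
                ) or (
                    fa in NEGATIVE_GROUP.get(f_res, ()) and pa in POSITIVE_GROUP.get(p_res, ())
                )
                if pos_neg and dist[(i, j)] <= criteria.saltbridge_max_dist:
                    salt = True
        hbond = False
        for i in fs:
            for j in ps:
                fa, pa = str(frames.atom_name[i]), str(frames.atom_name[j])
                da = (
                    fa in SIDECHAIN_DONORS.get(f_res, ())
                    and pa in SIDECHAIN_ACCEPTORS.get(p_res, ())
                ) or (
                    fa in SIDECHAIN_ACCEPTORS.get(f_res, ())
                    and pa in SIDECHAIN_DONORS.get(p_res, ())
                )
                if da and dist[(i, j)] <= criteria.hbond_max_dist:
                    hbond = True  # structure has no hydrogens: distance-only
        contact = min(dist.values()) <= criteria.contact_max_dist
        if salt:
            out.add((partner, "SALT_BRIDGE"))
        elif hbond:
            out.add((partner, "HBOND"))
        elif contact:
            out.add((partner, "CONTACT"))
    return out


class TestOccurrenceMatrix:
    def test_scripted_occupancy_half(self):
        pattern = tuple([True] * 10 + [False] * 10)
        sc = generate_interaction_script(20, [PartnerScript("A", 100, pattern)])
        m = build_occurrence_matrix(sc.frames, sc.focal, chain_roles=sc.chain_roles)
        assert m.partners == [("A", 100)]
        assert m.occupancy[0] == pytest.approx(0.5)
        np.testing.assert_array_equal(m.presence[0], np.array(pattern))

    def test_all_off_script_empty_matrix(self):
        sc = generate_interaction_script(10, [PartnerScript("A", 100, tuple([False] * 10))])
        m = build_occurrence_matrix(sc.frames, sc.focal, chain_roles=sc.chain_roles)
        assert m.partners == []
        assert intersubunit_summary(m) == {
            "gb1_partners": 0, "gb2_partners": 0,
            "max_cross_subunit_occupancy": 0.0, "threshold": 0.1,
        }

    def test_random_script_reproduced_elementwise(self):
        rng = np.random.default_rng(7)
        n = 30
        partners = [
            PartnerScript("A", 100, tuple(rng.random(n) < 0.5)),
            PartnerScript("A", 101, tuple(rng.random(n) < 0.5)),
            PartnerScript("B", 300, tuple(rng.random(n) < 0.5)),
        ]
        sc = generate_interaction_script(n, partners, chain_roles={"A": "GB1", "B": "GB2"})
        m = build_occurrence_matrix(sc.frames, sc.focal, chain_roles=sc.chain_roles)
        expected = {(p.chain_id, p.residue_number): np.array(p.pattern) for p in partners}
        got = {p: m.presence[i] for i, p in enumerate(m.partners)}
        assert set(got) == {k for k, v in expected.items() if v.any()}
        for key, pattern in got.items():
            np.testing.assert_array_equal(pattern, expected[key])

    def test_partners_sorted_by_descending_occupancy(self):
        n = 20
        partners = [
            PartnerScript("A", 100, tuple([True] * 5 + [False] * 15)),
            PartnerScript("B", 200, tuple([True] * 15 + [False] * 5)),
        ]
        sc = generate_interaction_script(n, partners)
        m = build_occurrence_matrix(sc.frames, sc.focal, chain_roles=sc.chain_roles)
        assert m.partners == [("B", 200), ("A", 100)]
        assert list(m.occupancy) == sorted(m.occupancy, reverse=True)

    def test_occupancy_monotone_under_empty_frames(self):
        pattern = tuple([True] * 10)
        sc_short = generate_interaction_script(10, [PartnerScript("A", 100, pattern)])
        sc_long = generate_interaction_script(
            20, [PartnerScript("A", 100, pattern + tuple([False] * 10))]
        )
        m_short = build_occurrence_matrix(sc_short.frames, sc_short.focal)
        m_long = build_occurrence_matrix(sc_long.frames, sc_long.focal)
        assert m_long.occupancy[0] <= m_short.occupancy[0]
        assert 0.0 <= m_long.occupancy[0] <= 1.0


class TestIntersubunitSummary:
    def test_gb1_vs_gb2_counts(self):
        n = 10
        partners = [
            PartnerScript("A", 100, tuple([True] * n)),
            PartnerScript("A", 101, tuple([True] * n)),
            PartnerScript("B", 300, tuple([True] * n)),
            PartnerScript("B", 301, tuple([True] * 8 + [False] * 2)),
            PartnerScript("B", 302, tuple([False] * n)),
        ]
        sc = generate_interaction_script(n, partners, chain_roles={"A": "GB1", "B": "GB2"})
        m = build_occurrence_matrix(sc.frames, sc.focal, chain_roles=sc.chain_roles)
        summary = intersubunit_summary(m)
        assert summary["gb1_partners"] == 2
        assert summary["gb2_partners"] == 2
        # focal sits on chain B; max cross-subunit occupancy is from chain A
        assert summary["max_cross_subunit_occupancy"] == pytest.approx(1.0)

    def test_no_gb1_partners_pattern(self):
        # the variant pattern: the focal side chain only reaches its own subunit
        n = 10
        partners = [
            PartnerScript("B", 300, tuple([True] * n)),
            PartnerScript("B", 301, tuple([True] * n)),
        ]
        sc = generate_interaction_script(n, partners, chain_roles={"A": "GB1", "B": "GB2"})
        m = build_occurrence_matrix(sc.frames, sc.focal, chain_roles=sc.chain_roles)
        summary = intersubunit_summary(m)
        assert summary["gb1_partners"] == 0
        assert summary["gb2_partners"] == 2


class TestCriteriaValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"hbond_max_dist": 0.0},
            {"hbond_min_angle": 0.0},
            {"hbond_min_angle": 181.0},
            {"scope": "BACKBONE"},
        ],
    )
    def test_invalid_criteria_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            InteractionCriteria(**kwargs)
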