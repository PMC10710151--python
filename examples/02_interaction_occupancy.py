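"""Build an interaction occurrence matrix for a focal residue.

Scripts a small trajectory in which the focal arginine (chain B, the GB2
subunit) forms a salt bridge with one GB1 partner for the first 60% of
frames and with one GB2 partner throughout, then recovers the occupancies
and the inter-subunit summary from the coordinates alone.
"""

from gpcrvar.interactions import build_occurrence_matrix, intersubunit_summary
from gpcrvar.synthetic import PartnerScript, generate_interaction_script

n_frames = 50
scripted = generate_interaction_script(
    n_frames,
    partners=[
        PartnerScript("A", 130, tuple([True] * 30 + [False] * 20)),  # GB1 side
        PartnerScript("B", 200, tuple([True] * 50)),                 # GB2 side
    ],
    focal=("B", 212),
    chain_roles={"A": "GB1", "B": "GB2"},
)

matrix = build_occurrence_matrix(
    scripted.frames, scripted.focal, chain_roles=scripted.chain_roles
)
print(f"focal residue: chain {matrix.focal[0]}, residue {matrix.focal[1]}")
for partner, subunit, occ in zip(matrix.partners, matrix.partner_subunit, matrix.occupancy):
    print(f"  partner {partner[0]}:{partner[1]} ({subunit}) occupancy {occ:.2f}")
print(intersubunit_summary(matrix))
print()
print("Occupancy is the fraction of frames with the bond present; a variant")
print("whose side chain turns away from GB1 loses all its GB1 partners.")
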