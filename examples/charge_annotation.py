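"""Charge annotation of a disordered N-terminal domain.

Computes the net charge of nested construct truncations at pH 7.4 and a
sliding-window charge profile, the classic way to visualize the
acidic-to-basic gradient along an IDR.
"""

from idrflex.sequence import charge_profile, net_charge, residue_inventory
from idrflex.synthetic import synthetic_ntd_sequence

seq = synthetic_ntd_sequence()  # labelled synthetic stand-in, residues 2-382
idr = seq.subsequence(2, 134, "IDR")

print(f"construct {seq.id}: residues {seq.first_residue_number}-"
      f"{seq.last_residue_number}")
for start in (2, 55, 98, 105, 121):
    sub = seq.subsequence(start, 134)
    z = net_charge(sub, pH=7.4)
    print(f"  IDR[{start:>3}-134]  net charge z = {z:+6.2f} e at pH 7.4")

prof = charge_profile(idr, pH=7.4, window=11)
most_basic = prof.positions[prof.window_charge.argmax()]
most_acidic = prof.positions[prof.window_charge.argmin()]
print(f"11-residue window charge: most acidic near residue {most_acidic}, "
      f"most basic near residue {most_basic}")
print("lysines from residue 50:", residue_inventory(seq, "K", 50))
# Negative net charge for long constructs reflects the acidic distal
# N-terminus; the basic maximum sits in the membrane-binding motif.
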