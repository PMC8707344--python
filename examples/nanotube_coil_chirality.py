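"""Supramolecular chirality of phenylalanine nanotube coils.

Loads the packaged per-molecule dipole tables (one 12-molecule coil of an
L-phenylalanine and a D-phenylalanine nanotube, dipoles from RM1 and Amber
calculations) and computes the coil chirality from the ordered dipole
vectors: c_total is the sum of the 10 consecutive triple products, c_norm
divides it by the cubed mean dipole magnitude.
"""

from chiracal import REFERENCE_TABLES, c_norm, load_reference_table

print(f"{'coil':26s} {'n':>2s} {'c_total':>9s} {'D_av':>6s} {'c_norm':>7s}  symbol")
for name in REFERENCE_TABLES:
    res = c_norm(load_reference_table(name))
    print(f"{name:26s} {res.n:2d} {res.c_total:9.3f} {res.d_av:6.3f} "
          f"{res.c_norm:7.3f}  {res.symbol}")
print()
print("c_total is in Debye^3; c_norm is dimensionless (scale-free).")
print("The L-F coils come out positive (D symbol) and the D-F coils negative")
print("(L symbol): the supramolecular level inverts the sign of chirality")
print("relative to the building blocks, as expected when moving up one level")
print("of hierarchical organization.")
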