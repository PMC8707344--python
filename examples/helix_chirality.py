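"""Chirality of an ideal helix: numeric sum vs the analytic closed form.

Builds one turn of a right-handed helix with alpha-helix-like dimensions
(radius 2.3 A, pitch 5.4 A, 10 steps), computes the triple-product
chirality numerically, compares it with the closed form, and shows why
the normalization exponent must be 5 by densifying the same turn.
"""

from chiracal import (
    IdealHelixSpec, generate_helix, chi_total, chi_norm,
    chi_closed_form, scaling_study,
)

spec = IdealHelixSpec(R=2.3, H=5.4, N=10)
chain = generate_helix(spec)

print(f"helix: R={spec.R} A, H={spec.H} A, N={spec.N} (-> {spec.n_points} points)")
print(f"chi_total numeric     : {chi_total(chain):.6f} A^3")
print(f"chi_total closed form : {chi_closed_form(spec):.6f} A^3")
print(f"chi_norm (k=5)        : {chi_norm(chain):.6f} A^-2  (positive -> right-handed)")
print()
print("densifying the same turn (chi/step^5 must approach a finite constant):")
table = scaling_study(2.3, 5.4, [10, 100, 1000, 10000], k=5)
print(table.to_string(index=False, float_format=lambda x: f"{x:.6g}"))
print()
print("The last column settles near 0.3201: with k=5 the normalized")
print("chirality of a fixed helix no longer depends on how densely the")
print("curve is sampled. Rerun with k=4 or k=6 to see it drift to 0 or blow up.")
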