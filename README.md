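# chiracal

Quantitative chirality of helical and irregular biomolecular structures
from scalar triple products.

Protein secondary structures — alpha-, 3₁₀- and pi-helices, alpha- and
beta-turns, omega-loops — are chiral objects, but the standard descriptors
(Ramachandran angles, DSSP classes) do not assign them a signed, continuous
handedness. `chiracal` implements a simple pseudoscalar measure built from
nothing but the ordered Cα positions of an element: for difference vectors
**v**ᵢ between successive Cα atoms,

```
chi_total = Σᵢ ([vᵢ, vᵢ₊₁], vᵢ₊₂)                    (Å³)
chi_norm  = Σᵢ ([vᵢ, vᵢ₊₁], vᵢ₊₂) / Cᵢ ,   Cᵢ = (mean of |vᵢ|,|vᵢ₊₁|,|vᵢ₊₂|)⁵
```

where `([a,b],c) = (a×b)·c` is the scalar triple product. Positive values
are right-handed (D), negative left-handed (L). The exponent 5 in the
normalization is not a free parameter: it is the unique power for which the
measure of a fixed helix tends to a finite nonzero constant as the curve is
sampled ever more densely (chi ~ |step|⁵ as the step length shrinks). The
package ships the ideal-helix generator and the closed-form expression
`chi = 16·(triples)·h·R²·sin⁴(φ/2)·sin(φ)` that make this argument exact
and testable.

The same construction applies one level up in the structural hierarchy:
for a helix-like peptide nanotube coil described by the ordered
dipole-moment vectors **D**ᵢ of its n constituent molecules,

```
c_total = Σᵢ₌₁..ₙ₋₂ ([Dᵢ, Dᵢ₊₁], Dᵢ₊₂)     (Debye³)
c_norm  = c_total / D_av³                  (dimensionless)
```

with `D_av` the mean dipole magnitude. Reference dipole tables for one
12-molecule coil of an L- and a D-phenylalanine nanotube (RM1 and Amber
dipoles) are packaged.

Intended users: structural bioinformaticians and molecular modellers who
want a signed handedness number per secondary-structure element or per
supramolecular coil, from a PDB file or a dipole table, with no fitting
and no reference structure.

## Worked example

```python
from chiracal import IdealHelixSpec, generate_helix, chi_total, chi_norm, chi_closed_form

spec = IdealHelixSpec(R=2.3, H=5.4, N=10)   # alpha-helix-like turn
chain = generate_helix(spec)
print(chi_total(chain), chi_closed_form(spec), chi_norm(chain))
```

prints

```
1.9597810011774925 1.959781001177492 0.24107043821150553
```

chi_total (Å³) from the numeric triple-product sum agrees with the closed
form to machine precision, and chi_norm is positive: a right-handed helix.
The nanotube side:

```python
from chiracal import load_reference_table, c_norm
res = c_norm(load_reference_table("phe_nanotube_LF_rm1"))
print(res.c_total, res.d_av, res.c_norm, res.symbol)
```

```
20.265977489999994 2.5524568918063275 1.218635848438296 D
```

The L-phenylalanine coil has c_total ≈ 20.27 Debye³ and c_norm ≈ +1.22 —
positive sign, D type — while the D-phenylalanine coil comes out negative
(L type): the sign of chirality alternates between levels of structural
organization. The scripts in `examples/` walk through each capability and
print annotated output.

## Command line

```
chiracal structure protein.pdb --range A:8-13 --stepwise   # per-element chirality map records
chiracal structure protein.pdb --from-helix-records        # every header-declared helix
chiracal dipole coil.csv --format json                     # nanotube coil from a dipole table
chiracal synth -R 2.3 -H 5.4 -N 18                         # ideal helix as CA-only PDB
chiracal synth -R 2.3 -H 5.4 -N 10 --scaling 5 10,100,1000 # normalization scaling study
```

Output is TSV (4 decimals) or JSON; handedness is reported as rh/lh/achiral.

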