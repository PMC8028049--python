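# reaxkit

A reactive force-field toolkit for aqueous iron–sulfur cluster chemistry.

Iron–sulfur clusters (FeS, Fe₂S₂, Fe₄S₄, …) are the active sites of
ferredoxins and other electron-transfer proteins, form the structural motifs
of pyrite and mackinawite, and are candidates for prebiotic catalysis.
Studying their stability in explicit water requires a potential that lets
bonds break and re-form as water molecules bind and leave the iron sites —
a *reactive* force field.  `reaxkit` is a self-contained Python
implementation of that workflow for H/O/Fe/S systems:

- **Potential** — a bond-order reactive potential with the full per-term
  decomposition

  `E = E_bond + E_lp + E_over + E_under + E_val + E_pen + E_coa + E_tors
     + E_conj + E_hbond + E_vdW + E_Coul + E_charge`

  where the bonded terms depend continuously on distance via corrected
  σ/π/ππ bond orders BO_ij, the nonbonded terms are tapered to zero (with
  three vanishing derivatives) at the cutoff radius, and partial charges are
  re-equilibrated at every evaluation by the electronegativity-equalization
  method (EEM): minimize Σᵢ(χᵢqᵢ + ηᵢqᵢ²) + E_Coul(q) subject to Σqᵢ = Q.
  Analytic forces are implemented for every term and verified against
  central differences to < 10⁻⁴ kcal mol⁻¹ Å⁻¹.
- **I/O** — the community-standard fixed-format `ffield` parameter file,
  (extended-)XYZ structures with orthorhombic cells, multi-frame trajectory
  files, and a diffable TSV training-set format; all with round-trip tests.
- **Dynamics** — L-BFGS geometry optimization to a root-mean-square-gradient
  (RMSG) criterion, and velocity-Verlet NVT dynamics with a Berendsen
  thermostat (λ = √(1 + (dt/τ)(T₀/T − 1))); periodic boxes smaller than
  twice the cutoff are handled by explicit image enumeration.
- **Training** — internal-coordinate scans (bonds, angles, torsions, rigid
  cluster–water separations) that distort exactly one coordinate at a time;
  the weighted least-squares cost C(p) = Σₘ wₘ (yₘᶠᶠ − yₘʳᵉᶠ)²; and a
  particle-swarm optimizer (c₁ = c₂ = 2.0, inertia 0.9 → 0.4) with
  Gaussian-mutation respawn of poor agents (γ = 0.1) and periodic
  Nelder–Mead polish, with train/validation partitioning.
- **Analysis** — permutation–inversion-minimized RMSD (Hungarian assignment
  alternated with Kabsch alignment, both parities), hydrogen-bond counting
  with 3.7 Å / 20° donor–acceptor criteria, windowed trajectory statistics
  (pooled Fe–S distances, folded ring dihedral, cluster–water H-bond count),
  symmetry-unique geometry-deviation reports, and correlation/charge tables.
- **Fixtures** — a deterministic toy H/O/Fe/S force field, reference
  geometries, a solvated-box packer (one Fe₂S₂ + 78 waters in the
  13.0 × 16.4 × 15.24 Å production cell), and synthetic training sets
  generated from a known force field for parameter-recovery testing.

See `docs/methods.md` for the precise functional forms, numerical choices,
and limitations.

## Worked example

```python
from reaxkit import compute_energy, equilibrate_charges, fixtures

ff = fixtures.make_toy_forcefield(elements=("H", "O"))
water = fixtures.water()
print(compute_energy(water, ff).as_dict())
print(equilibrate_charges(water, ff))
```

prints (kcal/mol and electrons)

```
e_bond  -260.149945   e_over  -9.047342   e_under -0.491584
e_val      1.236903   e_vdw   51.628366   e_coul -81.285084
e_charge  47.295252   total -250.813434
charges:  O -0.617331   H +0.308665   H +0.308665
```

The O–H bonds contribute the large attractive `e_bond`; shielded van der
Waals repulsion and tapered Coulomb attraction balance it near equilibrium;
the charges sum to the molecule's total charge (0) and equalize the
effective electronegativities.  Relaxing this molecule gives O–H = 0.94 Å
and ∠HOH = 95.6°, and a parameter-recovery run
(`examples/03_scan_and_recover.py`) refits the O–H σ-bond dissociation
energy from a bond-scan training set to its generating value,
`De_sigma = 160.0000 kcal/mol`, with a monotonically non-increasing swarm
cost.

The `examples/` directory contains one short narrative script per
capability: energy/charges, relaxation + NVT dynamics, scan-based training
and parameter recovery, the solvated Fe₂S₂ box with hydrogen-bond and
coordination analysis, and structure alignment/reporting.

A thin command-line interface mirrors the library:

```sh
reaxkit fixtures ffield -o ffield.toy
reaxkit fixtures box --waters 78 -o box.xyz
reaxkit energy box.xyz --ffield ffield.toy --breakdown
reaxkit md box.xyz --ffield ffield.toy --temp 300 --steps 1000 --seed 1
reaxkit analyze stats trajectory.xyz --window 40 80 --cluster 0,1,2,3
```

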