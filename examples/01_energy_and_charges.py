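"""Evaluate the reactive potential on a water molecule.

Builds the bundled toy H/O force field, computes the per-term energy
breakdown (kcal/mol) and the EEM partial charges (e), and prints both.
The breakdown terms sum exactly to the total; the charges sum to the
molecule's total charge and are negative on oxygen, positive on hydrogen.
"""

from reaxkit import compute_energy, equilibrate_charges, fixtures

ff = fixtures.make_toy_forcefield(elements=("H", "O"))
water = fixtures.water()

breakdown = compute_energy(water, ff)
print("energy breakdown (kcal/mol):")
for name, value in breakdown.as_dict().items():
    if abs(value) > 1e-12 or name == "total":
        print(f"  {name:10s} {value:14.6f}")

charges = equilibrate_charges(water, ff)
print("\nEEM charges (e):")
for sym, q in zip(water.symbols, charges):
    print(f"  {sym:<2s} {q:+.6f}")
print(f"  sum = {charges.sum():+.2e}  (equals the total charge)")
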