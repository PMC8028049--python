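"""Solvate Fe2S2 in water, run a short NVT trajectory, and analyse it.

Packs 78 waters around the cluster in the 13.0 x 16.4 x 15.24 A periodic
box (238 atoms), runs 20 fs of thermostatted dynamics at 300 K, and reports
windowed means of the Fe-S skeleton distance, the ring dihedral, the
cluster-water hydrogen-bond count (3.7 A / 20 degree criteria), and the
water coordination state of each iron site.

This is a scaled-down illustration of the full solvation protocol (16 ps
with analysis over the last 10 ps), which runs through exactly the same
calls with a larger ``n_steps``.  Cluster-water hydrogen bonds need
picosecond-scale water reorientation to appear, so the tens-of-femtoseconds
run shown here typically reports a count near zero; the total water-water
count is already well sampled.
"""

from reaxkit import fixtures
from reaxkit.analysis import (HBondCriteria, classify_fe_coordination,
                              trajectory_statistics)
from reaxkit.dynamics import MDConfig, run_md

ff = fixtures.make_toy_forcefield()
box = fixtures.build_solvated_box(fixtures.BoxSpec(
    cell=(13.0, 16.4, 15.24), n_waters=78, solute=fixtures.fe2s2(), seed=7))
print("box: %d atoms in %.1f x %.1f x %.1f A" % (len(box), *box.cell))

# a loose pre-relaxation settles the packed waters before dynamics
from reaxkit.dynamics import MinimizationError, minimize_structure
try:
    box = minimize_structure(box, ff, rmsg_tol=1.0, max_iter=80)
except MinimizationError as err:
    box = err.best

cfg = MDConfig(timestep_fs=0.1, temperature=300.0, berendsen_tau_fs=25.0,
               n_steps=200, seed=7, record_every=10)
traj = run_md(box, ff, cfg)

stats = trajectory_statistics(
    traj, window=(10.0, traj.frames[-1].time_fs),
    distances={"d(Fe-S)": [(0, 2), (0, 3), (1, 2), (1, 3)],
               "d(Fe-Fe)": [(0, 1)]},
    dihedrals={"theta(Fe-S-Fe-S)": (0, 2, 1, 3)},
    hbond_cluster={0, 1, 2, 3}, crit=HBondCriteria())
print("\nwindowed statistics (mean +- population SD):")
for name, (mean, sd) in stats.stats.items():
    print(f"  {name:18s} {mean:8.3f} +- {sd:.3f}")

from reaxkit.analysis import count_hbonds
total = count_hbonds(traj.frames[-1].structure, crit=HBondCriteria())
print(f"\ntotal hydrogen bonds in the final frame (incl. water-water): {total}")
coord = classify_fe_coordination(traj.frames[-1].structure, fe_indices=(0, 1))
print(f"Fe-O coordination in the final frame: {coord} "
      "(3/4/5 = trigonal/tetrahedral/bipyramidal)")
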