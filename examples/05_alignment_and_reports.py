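"""Compare structures and force-field predictions.

Shows the permutation-inversion minimized RMSD (zero for a rotated,
permuted, inverted copy; positive once the geometry is perturbed), a
symmetry-unique deviation report between a distorted and a reference
cluster, and the correlation summary of force-field energy predictions
against reference values.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from reaxkit import Structure, fixtures
from reaxkit.analysis import (aligned_rmsd, geometry_deviation_report,
                              prediction_correlation_report)
from reaxkit.training import ScanSpec

cluster = fixtures.fe2s2_w4()
rng = np.random.default_rng(0)
rot = Rotation.random(random_state=4).as_matrix()
perm = rng.permutation(len(cluster))
copy = Structure([cluster.symbols[p] for p in perm],
                 ((-cluster.coords) @ rot.T + 5.0)[perm])
print(f"RMSD to a rotated+permuted+inverted copy: "
      f"{aligned_rmsd(cluster, copy):.2e} A")

distorted = cluster.with_coords(
    cluster.coords + 0.05 * rng.normal(size=cluster.coords.shape))
print(f"RMSD to a 0.05 A jiggled copy:            "
      f"{aligned_rmsd(cluster, distorted):.4f} A")

rep = geometry_deviation_report({"fe2s2w4": distorted}, {"fe2s2w4": cluster})
b, a = rep.aggregate["bond"], rep.aggregate["angle"]
print(f"deviations over symmetry-unique coordinates: "
      f"bonds {b[0]:.4f} +- {b[1]:.4f} A, angles {a[0]:.3f} +- {a[1]:.3f} deg")

ff = fixtures.make_toy_forcefield(elements=("H", "O"))
ts = fixtures.make_synthetic_trainset(
    ff, {"w": fixtures.water()},
    [("w", ScanSpec(("bond", (0, 1)), 0.1, (-0.1, 0.4), (1,)))],
    include_charges=False)
corr = prediction_correlation_report(ts, ff)["summary"]["train"]
print(f"self-consistent energy correlation: slope {corr['slope']:.6f}, "
      f"R^2 {corr['r2']:.6f} (identity line, as expected)")
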