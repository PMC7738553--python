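"""Synthetic time-lapse: division orientation, migration, proliferation.

Generates a 15 h movie (5 min frames) of dense interstripe and loose
stripe iridophores, then runs the three behaviour statistics: axial
division-plane stats with a Rayleigh uniformity test, net-migration
bias of cells moving at least one cell diameter (20 um), and per-class
proliferation rates with a loose/dense rate-ratio test.
"""
import json

from iridoptics import generate_tracks
from iridoptics.pipeline import analyze_tracks

dataset = generate_tracks(n_dense=300, n_loose=300, rng_seed=1)
report = analyze_tracks(dataset, min_displacement_um=20.0, rng_seed=1)

print(json.dumps(report, indent=2))
print(
    "\nDense (interstripe) divisions align with the AP axis (mean axis near 0,"
    "\nlow Rayleigh p); loose (stripe) divisions are uniform (high p).  Loose"
    "\ncells drift ventrally - away from the interstripe (negative DV mean with"
    "\nCI excluding 0) - and divide about twice as often as dense cells."
)
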