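"""Silencing hub cells in a small coupled islet.

Builds a 120-cell mouse-like islet with 10% hubs (glucose 11 mM) among
near-threshold non-hubs (U(6,7) mM), coupled by bimodal gap junctions
(hub edges ~50 pS, non-hub edges ~10 pS).  Clamps 6% of the islet —
drawn from the hubs — at −100 mV for 30 s and prints how whole-islet
Ca²⁺ activity changes, then recovers.

Run:  python examples/hub_silencing.py     (~2 min)
"""

import numpy as np

from islethub import (SimulationProtocol, assemble_network,
                      binarize_traces, activity_metrics,
                      generate_mouse_like, run_protocol)
from islethub.engine import nested_inhibition_sets

arch = generate_mouse_like(120, rng_seed=0)
net = assemble_network(arch, master_seed=0, gj_mode="bimodal")
print(f"islet: {net.n_cells} cells, {len(net.hubs)} hubs, "
      f"{net.gap_junctions.n_edges} gap junctions")

(inhibited,) = nested_inhibition_sets(net, [6.0], target="hub", rng=0)
proto = SimulationProtocol(equilibration_s=40, baseline_s=30,
                           inhibition_s=30, recovery_s=30, rtol=1e-5,
                           inhibited=tuple(int(c) for c in inhibited))
res = run_protocol(net, proto)

raster = binarize_traces(res.ca, res.time_s,
                         baseline_mask=res.epoch_mask("baseline"))
mca = res.mean_ca()
for epoch in ("baseline", "inhibition", "recovery"):
    amp = np.ptp(mca[res.epoch_mask(epoch)])
    print(f"{epoch:11s}: islet-mean Ca²⁺ amplitude {amp:.3f} µM")
m = activity_metrics(res, raster, "inhibition")
print(f"\nactivity during inhibition of {len(inhibited)} hub cells "
      f"(6% of the islet):")
print(f"  amplitude {m['amplitude']:.0f}% of baseline  |  "
      f"summed {m['summed']:.0f}% of baseline")
print("Clamping a few strongly-coupled, highly metabolic hubs collapses "
      "the coordinated\nwhole-islet oscillation; releasing the clamp "
      "restores it.")
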