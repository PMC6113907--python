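"""Synthetic islet architectures and their contact statistics.

Generates a mouse-like (dense sphere) and a human-like (clustered) islet,
builds the 17.5 µm contact graph for each, and prints the contact-number
statistics that distinguish the two architectures.

Run:  python examples/build_islet.py     (~5 s)
"""

from islethub import (build_contact_graph, contact_statistics,
                      generate_human_like, generate_mouse_like)

mouse = generate_mouse_like(750, rng_seed=1)
human = generate_human_like(750, rng_seed=1)

for arch in (mouse, human):
    graph = build_contact_graph(arch)          # contact iff distance < 17.5 µm
    stats = contact_statistics(graph)
    top = sorted(stats["degree_histogram"].items())
    print(f"{arch.species_label:11s} islet: {arch.n_cells} cells, "
          f"{stats['n_edges']} contacts, "
          f"mean {stats['mean_degree']:.1f} contacts/cell")
    print(f"             degree histogram (deg: cells): "
          f"{dict(top[:12])} ...")

print("\nMouse-like islets pack β-cells into one dense core (~10 contacts "
      "per cell);\nhuman-like islets split them into touching sub-clusters "
      "(~8 contacts per cell),\nwhich is why human islets are more fragile "
      "to hub loss.")
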