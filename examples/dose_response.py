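"""Hub vs non-hub dose-response with a sigmoid IC50 fit.

Runs the desk-scale hub-vs-nonhub experiment: one 120-cell bimodal islet,
inhibited fractions 0–7.5% of the islet drawn either from hubs or from
non-hubs, coordinated-activity amplitude quantified against baseline and
fit with a decreasing logistic A(x) = 100/(1+exp((x−x0)/k)).

Run:  python examples/dose_response.py     (~6 min)
"""

from islethub import desk_scale_config, experiment_hub_vs_nonhub

cfg = desk_scale_config()
out = experiment_hub_vs_nonhub(cfg)

for target, dr in out["dose_responses"].items():
    pts = ", ".join(f"{f:.1f}%→{a:.0f}%"
                    for f, a in zip(dr.fractions_pct, dr.activity_pct))
    print(f"{target:7s}: {pts}")
    print(f"         IC50 x0 = {dr.x0:.2f}% of islet, slope k = {dr.k:.2f},"
          f" R² = {dr.r2:.2f}")

hub = out["dose_responses"]["hub"]
non = out["dose_responses"]["nonhub"]
print(f"\nhub IC50 ({hub.x0:.1f}%) < non-hub IC50 ({non.x0:.1f}%): "
      "silencing a few strongly-coupled hubs is far more disruptive than "
      "silencing the same number of ordinary cells.")
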