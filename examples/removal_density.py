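"""Two-pass removal abundance and density estimation.

With catches c1 and c2 from two consecutive electrofishing passes, the
closed-form estimates are N = c1^2/(c1-c2) and p = 1 - c2/c1; densities are
scaled to fish per hectare over the stream surface.
"""

import vitalrates as vr

# a single worked cell: 100 fish in pass 1, 10 in pass 2
est = vr.two_pass_estimate(100, 10)
print(f"c1=100, c2=10  ->  N = {est.n_hat:.2f} +- {est.se_n:.2f}, "
      f"p = {est.p_hat:.2f}, density = {est.density_ha:.0f} fish/ha")

# published-style conversion: 548 fish on 746.27 m^2
print(f"548 fish on 746.27 m^2 -> {vr.density_from_abundance(548):.0f} fish/ha")
print()

# full density table from a simulated dataset
cfg = vr.SimConfig(seed=1)
enc, truth = vr.simulate_population(cfg)
tab = vr.density_table(enc, strata="age_class", area_m2=cfg.area_m2)
print(tab.head(8).to_string(index=False))
print()
older = tab[(tab.stratum == ">0+") & (tab.method == "closed-form")]
print(f"mean per-pass capture probability (>0+): {older['p_hat'].mean():.2f}")
print("With two passes at ~0.9 per pass, nearly every fish present is seen,")
print("so estimated and true abundance track each other closely.")
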