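"""Helicase enzymology: every curve model fitted on generated fixtures.

Generates one noise-free curve per assay family, refits it and prints the
parameters, plus the closed-form desk numbers (AUC buoyancy, cellular mRNA
concentration).
"""

from agmotif import enzymology as enz
from agmotif import synthetic as syn

fx = syn.gen_enzymology(syn.SimulationSpec(seed=1))

p = fx["progress"]["data"]
fit = enz.fit_progress_curve(p["time"], p["signal"])
print(f"unwinding: amplitude {fit.amplitude:.3f}, k_obs {fit.k_obs:.3f}/min,"
      f" initial rate {fit.initial_rate:.3f}/min")

h = fx["hill"]["data"]
hf = enz.hill_fit(h["conc"], h["response"])
print(f"titration: K_1/2 {hf.k_half:.2f} uM, Hill h {hf.h:.2f} "
      f"(h > 1: cooperative, multiple subunits)")

d = fx["decay"]["data"]
df_ = enz.exp_decay_fit(d["time"], d["signal"])
print(f"complex stability: half-life {df_.half_life:.2f} min")

m = fx["mixing"]["data"]
mix = enz.fit_mixing(m["f_inactive"], m["rel_activity"])
print(f"wt/inactive mixing: best model {mix['model']} with n = "
      f"{mix['n_hat']} subunits per active complex")

a = fx["atpase"]["data"]
rate = enz.atpase_rate(a["time"], a["signal"])
print(f"ATPase: {rate:.3f} mM ATP/min from the NADH-coupled A340 slope")

print(f"FRET of (F565, F665) = (1, 1): {enz.fret_efficiency(1, 1):.2f}")
vbar = enz.vbar_complex(2, 46000, 0.73, 10000, 0.53)
print(f"partial specific volume of a 2:1 protein:RNA complex: {vbar:.3f} mL/g")
conc = enz.mrna_concentration(300000, 2425)
print(f"total cellular mRNA concentration: {conc * 1e6:.3f} uM (< 1 uM)")
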