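"""Pulsed-SILAC translation-rate fitting and dependence classification.

Simulates a TMT pulse-labelling cohort (4 replicates, 0/2/4/8 h) in which a
quarter of the proteins halve their translation rate under helicase
inhibition, fits ln F_H = k*t + offset per protein and condition, and
classifies dependence by BH FDR of the rate difference.
"""

from agmotif import synthetic as syn
from agmotif.pipeline import run_psilac_pipeline

spec = syn.SimulationSpec(seed=7)
table, truth = syn.gen_psilac(spec)
res = run_psilac_pipeline(table)

print("counts:", res["counts"])
dep = res["dependence"].merge(truth[["protein_id", "dependent"]],
                              on="protein_id")
called = dep.loc[dep["label"] == "dependent"]
print(f"sensitivity for planted subset: "
      f"{(called['dependent'].sum() / truth['dependent'].sum()):.2f}")
print(called[["protein_id", "k_ctrl", "k_treat", "log2fc", "fdr"]]
      .head(5).to_string(index=False))
print(
    "\n'dependent' proteins (FDR < 0.1) show log2fc near -1, the planted\n"
    "rate halving; 'independent' proteins (FDR > 0.7) cluster at log2fc 0."
)
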