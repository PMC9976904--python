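"""Motif-anchored DMS-reactivity window analysis on a synthetic cohort.

Builds a transcriptome with planted purine-rich (R10) motifs and paired
control/helicase-inhibited reactivity profiles carrying a localized
structure gain downstream of each motif, then runs the full analysis arm.
"""

from agmotif import synthetic as syn
from agmotif.pipeline import run_structure_pipeline

spec = syn.SimulationSpec(seed=7)
transcripts, truth = syn.gen_transcriptome(spec)
ctrl, treat = syn.gen_reactivity_pair(transcripts, truth, spec)
res = run_structure_pipeline(transcripts, ctrl, treat, {"seed": 7})

print("filter counts:", res["counts"])
print(res["test_summary"].to_string(index=False))
print(
    "\nA negative median motif delta with a small p-value only on the\n"
    "downstream side means reactivity (single-strandedness) drops 31-50 nt\n"
    "3' of the motifs when the helicase is inhibited - i.e. localized RNA\n"
    "structure gain - while random windows and upstream windows stay flat."
)
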