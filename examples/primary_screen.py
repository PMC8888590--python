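"""Simulate and analyse a primary dual-readout screen.

Generates a desk-scale 4-plate screen (duplicate plates, three arms,
planted effect classes), normalizes every well to its plate's
non-targeting controls, calls hits with robust z-scores, and compares
the calls with the planted truth.
"""

import glycoscreen as gs
from glycoscreen.simulate import recovery_metrics

cfg = gs.SimulationConfig(
    n_plates=4,
    seed=42,
    class_fractions={"neutral": 0.85, "lethal": 0.05,
                     "glycolysis_low": 0.05, "vem_enhancer_lactate": 0.05},
)
dataset, truth = gs.generate_screen(cfg)
print(f"simulated {cfg.n_plates} plates, "
      f"{len(dataset.measurements)} well measurements, "
      f"{len(truth)} library genes")

summary, controls = gs.summarize_genes(dataset)
hit_table, zscores = gs.call_hits(summary)
report = gs.hit_report(hit_table)

print("\nhit counts (genes passing each predicate):")
for flag, n in report["counts"].items():
    print(f"  {flag:22s} {n}")
print("planted per class:", truth["class_name"].value_counts().to_dict())
print("(no viability-enhancer class is planted here: that flag's calls are")
print(" chance crossings of the drug-arm growth contrast, whose threshold")
print(" has no published value)")

print("\nrecovery of planted classes (sensitivity / specificity):")
rec = recovery_metrics(hit_table, truth)
print(rec.to_string(index=False))
print("\nsensitivity: fraction of planted genes the pipeline flags;")
print("specificity: fraction of other genes it correctly leaves unflagged.")
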