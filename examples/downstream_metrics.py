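"""Follow-up metrics: polysome profiles, proliferation, patient data.

Shows the small computations used downstream of the screen: percent
distribution of a 14-fraction sucrose-gradient profile, the
sub-polysome/polysome ratio (rises when translation is suppressed),
doublings-per-day proliferation rate, and the per-gene percent of
patients upregulating a gene set on progression.
"""

import numpy as np

import glycoscreen as gs

# translationally active profile: most signal in polysome fractions 9-14
active = np.array([1, 1, 2, 2, 2, 3, 3, 4, 8, 9, 10, 9, 8, 6], dtype=float)
# suppressed profile: signal collapses into sub-polysome fractions 3-8
suppressed = np.array([3, 4, 8, 9, 9, 8, 7, 6, 3, 2, 1, 1, 1, 1], dtype=float)

for name, prof in (("active", active), ("suppressed", suppressed)):
    dist = gs.fraction_distribution(prof)
    ratio = gs.sub_poly_ratio(prof)
    print(f"{name:10s} polysome share {dist[8:].sum():5.1f}%  "
          f"sub-polysome/polysome ratio {ratio:.2f}")
print("a ratio > 1 means most material sits outside polysomes: global")
print("translation is suppressed.\n")

rate = gs.proliferation_rate(day5_count=16 * 450, day0_count=450)
print(f"16-fold growth over 4 days = {rate:.2f} doublings/day")

genes = [f"G{i:02d}" for i in range(23)]
frac = {g: 0.15 for g in genes[:18]} | {g: 0.0 for g in genes[18:]}
expr = gs.simulate_patient_expression(genes, n_patients=40, frac_up=frac, seed=1)
percent, summary = gs.patient_upregulation(expr, up_threshold=1.5)
print(f"\n{summary['n_above_cutoff']} of {summary['n_genes']} genes "
      f"({summary['percent_of_genes']:.0f}%) upregulated in >=10% of patients")
print("(upregulated: progression/pre-treatment expression ratio > 1.5)")
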