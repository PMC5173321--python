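"""Negative-binomial differential expression on the irradiation time course.

Filters low-expression clusters (CPM >= 1 in >= 3 samples), normalises with
median-of-ratios size factors, estimates shrunken NB dispersions, and runs the
exact conditional test of 12 h post-irradiation versus control.
"""

import pandas as pd

import neoblastsig as nb

config = nb.SimulationConfig(n_clusters=1500, designs=("irradiation",), seed=2)
counts, sheet, truth = nb.simulate_counts(config)

filtered = nb.cpm_filter(counts)
print(f"{len(counts)} clusters, {len(filtered)} pass the CPM filter")

sf = nb.estimate_size_factors(filtered)
print("size factors:", ", ".join(f"{s:.3f}" for s in sf))

t12 = list(sheet.index[sheet["timepoint_h"] == 12])
t0 = list(sheet.index[sheet["timepoint_h"] == 0])
disp = nb.estimate_dispersion(filtered, sf, groups=[t12, t0])
print(f"common NB dispersion: {disp.phi_common:.3f} (simulated truth 0.1)")

res = nb.nb_exact_test(filtered, sf, disp, t12, t0, contrast="irr_12h_vs_0h")
down = res.down
prog = pd.Series(truth.cluster_program)
frac_prolif = sum(prog[c] in ("neoblast", "germline") for c in down) / len(down)
print(f"\n{len(down)} clusters down at FDR 0.05; "
      f"{frac_prolif:.1%} are true proliferating-cell programs")
print("\nmost depleted clusters:")
print(res.table.nsmallest(5, "log2fc").round(3).to_string())
print("\nstrong negative log2FC with tiny FDR = transcripts lost with the"
      "\nablated proliferating cells.")
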