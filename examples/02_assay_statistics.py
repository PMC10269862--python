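"""Persistence-assay statistics on simulated colony counts: censoring,
vial filters, the Kruskal-Wallis omnibus test, and Dunn's post hoc
significance letters.

Run examples/01_simulate_inputs.py first.
"""

import pandas as pd

from flymgwa import assay

records = assay.read_cfu_tsv("example_data/cfu_records.tsv")
retained, exclusions = assay.filter_vials(records)
print(f"{len(records)} fly records; {len(exclusions)} vials excluded:")
print(exclusions.to_string(index=False) if not exclusions.empty else "  (none)")

retained = assay.add_cfu_columns(retained)
groups = {s: g["log_cfu"].to_numpy() for s, g in retained.groupby("strain")}

omnibus = assay.kruskal_wallis(groups)
print(
    f"\nKruskal-Wallis over {len(groups)} strains: "
    f"H = {omnibus.statistic:.2f}, df = {omnibus.df}, p = {omnibus.p:.3g}"
)
# A small p says strains differ in how well they persist in the fly.

table, letters = assay.dunn_posthoc(groups, adjust="bh", alpha=0.05)
print("\nsignificance letters (strains sharing a letter are not distinguishable):")
summary = pd.DataFrame(
    {
        "mean_log_cfu": {s: v.mean() for s, v in groups.items()},
        "letters": letters,
    }
).sort_values("mean_log_cfu")
print(summary.round(2).to_string())
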