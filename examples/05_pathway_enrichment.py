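"""KEGG pathway enrichment of the significant genes from the association
scan: per-pathway 2x2 chi-square with Benjamini-Hochberg FDR control.

Run examples/01_simulate_inputs.py and 04_run_association.py first.
"""

import json

import pandas as pd

from flymgwa import assign_pathways, enrich
from flymgwa.simulate import read_annotation_tsv

annotation = assign_pathways(read_annotation_tsv("example_data/annotation.tsv"))
mgwa = pd.read_csv("example_data/mgwa_results.tsv", sep="\t")
significant = set(mgwa.loc[mgwa["significant"], "og_id"])
significant &= annotation.annotated_ogs()

out = enrich(significant, annotation, alpha=0.05)
print(f"{len(significant)} significant annotated OGs against "
      f"{len(annotation.annotated_ogs())} annotated background OGs")
print("\nper-pathway enrichment (a = significant OGs in pathway):")
cols = ["pathway_id", "a", "expected_a", "chi2", "raw_p", "fdr_q", "enriched"]
print(out[cols].round(4).to_string(index=False))

truth = json.load(open("example_data/truth.json"))
print(f"\nplanted enriched pathway: {truth['enriched_pathways']}")
print(f"top hit: {out.iloc[0]['pathway_id']} (q = {out.iloc[0]['fdr_q']:.3g})")
# `enriched` requires both q < 0.05 and an observed overlap above its
# expectation, so depleted pathways are never called enriched.
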