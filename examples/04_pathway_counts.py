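"""Project predicted binding sites onto flowering-pathway gene lists.

Builds a toy pathway definition (photoperiod PH, vernalization VE and
pathway-integration PI genes), assigns predicted sites to genes and prints
the per-gene, per-family count table and the family totals in the
conventional "sites (genes)" form.
"""

from promscan import PathwayDefinition, family_totals, map_sites
from promscan.scan import PredictedSite


def site(gene, family, start=1):
    return PredictedSite("m1", "tf", family, gene, start, start + 9, "+", 5.0, 1e-5,
                         q_value=0.01, species="syn")


pathway = PathwayDefinition(
    "syn",
    [
        ("gene01", "CO", "PH", "circadian clock"),
        ("gene02", "VRN1", "VE", "vernalization"),
        ("gene03", "FT", "PI", "integrator"),
        ("gene04", "LFY", "PI", "integrator"),
    ],
)

sites = (
    [site("gene01", "MADS box", 10 * i) for i in range(3)]
    + [site("gene01", "CSD", 100)]
    + [site("gene03", "MADS box", 10 * i) for i in range(4)]
    + [site("gene03", "AP2", 200)]
)

table = map_sites(sites, pathway, promoter_gene_ids=["gene01", "gene02", "gene03"])
print("per-gene counts (columns: TF families, total, no_promoter flag):")
print(table.to_string())
print()
totals = family_totals(table)
print("family totals, 'sites (genes)':")
for _, row in totals.iterrows():
    print(f"  {row['tf_family']:>9}: {row['formatted']}")
print()
print("gene04 has no promoter in this toy set, so its zero row carries the")
print("no_promoter flag — the '(0)' convention for genes whose upstream region")
print("could not be retrieved.")
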