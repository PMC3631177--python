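"""Category fold enrichment: the cell-cycle over-representation arithmetic.

Replays the published worked example: 117 of 341 screen hits annotated
"cell cycle" against 2,044 of 54,613 probe sets on the platform.
"""

from anchorsig import fold_enrichment
from anchorsig.datasets import U133_PLUS2_CELL_CYCLE, U133_PLUS2_PROBES

broad = fold_enrichment(117, 341, U133_PLUS2_CELL_CYCLE, U133_PLUS2_PROBES, category="cell cycle")
print(f"broad screen:     {broad.hits_in_category}/{broad.hits_total} hits = {broad.hit_percent:g}%")
print(f"platform:         {broad.background_in_category}/{broad.background_total} = {broad.background_percent:g}%")
print(f"fold enrichment:  {broad.fold:.2f}  (hypergeometric p = {broad.hypergeom_p:.3g})")

stringent = fold_enrichment(18, 26, U133_PLUS2_CELL_CYCLE, U133_PLUS2_PROBES, category="cell cycle")
print(f"\nstringent screen (r >= 0.72): {stringent.hit_percent:g}% of hits, {stringent.fold:.1f}-fold")
# fold = (hit fraction) / (background fraction): >1 means the category is
# over-represented among the anchor-correlated genes relative to the array.
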