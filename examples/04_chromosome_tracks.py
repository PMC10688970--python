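"""Chromosome-scale binned tracks and the Y-activation contrast.

Exports 20-kb binned CPM coverage for a somatic and a spermatocyte
library and their per-bin log2 ratio — the data layer behind
chromosome-painting displays.  The planted Y factor switches from ~0
(heterochromatic, silent in soma) to ≫1 (activated in spermatocytes), so
the log2 ratio should be positive across essentially all Y bins.
"""

from germtag import synth
from germtag.quant import binned_coverage, log2_bin_ratio, transposon_scores

config = synth.SyntheticConfig()
ann = synth.simulate_annotation(config, seed=5)
wing = synth.simulate_fragment_library(config, ann, "wing", seed=30)
sperm = synth.simulate_fragment_library(config, ann, "spermatocyte", seed=31)

ratio = log2_bin_ratio(binned_coverage(sperm), binned_coverage(wing), pseudocount=1.0)
for chrom in ann.chrom_sizes:
    vals = ratio.chrom_values(chrom)
    print(f"{chrom}: {len(vals)} bins, mean log2(spermatocyte/wing) = {vals.mean():+.2f}, "
          f"positive in {(vals > 0).mean():.0%}")
# Y shows a strongly positive ratio in ~100% of bins (activation); the X
# drops (its somatic compensation is absent in spermatocytes).

# Transposon consensi are scored the same way, each consensus as one
# full-length interval, CPKM-scaled:
table = synth.simulate_transposon_table(config, 6, n_consensi=5)
te_lib = synth.simulate_consensus_fragments(
    config, table, "spermatocyte", seed=32, element_factors={table.index[0]: 20.0}
)
print()
print(transposon_scores(te_lib, table).round(2).to_string())
# The first element carries a planted 20x activation factor and stands
# out in CPKM against the rest of the panel.
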