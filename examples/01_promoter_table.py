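"""Build a promoter table from gene models.

Simulates a small annotation, derives one promoter per distinct
(gene, TSS) pair — minimum transcript coordinate on '+', maximum on '−' —
attaches the −200..+500 bp scoring window, and flags promoters with a
second gene's promoter within 1 kb upstream (those are excluded from
average-profile displays to avoid overlapping signals).
"""

from germtag import synth
from germtag.annotation import derive_promoters, parse_gene_models, promoter_table

config = synth.SyntheticConfig()
ann = synth.simulate_annotation(config, seed=1)
transcripts = parse_gene_models(ann.to_gtf())
promoters = derive_promoters(transcripts)
table = promoter_table(promoters, ann.chrom_sizes)

print(f"{len(transcripts)} transcripts -> {len(promoters)} promoters")
print(table.head(5).to_string(index=False))
crowded = table["upstream_within_1kb"].sum()
print(f"\n{crowded} promoters have another gene's promoter within 1 kb upstream")
# Each row: 1-based TSS, strand, the 0-based half-open 701-bp scoring
# window, and the nearest different-gene promoter 5' of the TSS.
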