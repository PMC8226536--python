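"""Discover and classify processed-pseudogene copies of a cDNA.

Builds a synthetic genome in which a 10-exon parent gene has five
intronless copies (4-13% diverged, some truncated or reading-frame broken)
and one intron-retaining paralog, then rediscovers and classifies every
locus from the cDNA alone.
"""

from pseudoquant.homology import catalog_report, classify_locus, find_homologous_loci
from pseudoquant.synthetic import default_locus_config, generate_locus_set

locus_set = generate_locus_set(default_locus_config(seed=17))
hits = find_homologous_loci(locus_set.cdna, locus_set.genome)
classifications = [
    classify_locus(
        hit, locus_set.gene_model, locus_set.cds, locus_set.genome, cdna=locus_set.cdna
    )
    for hit in hits
]
print(catalog_report(classifications).to_string(index=False))

# One row per homologous locus: the parent gene first (identity 100%, it
# chains across its own introns), then the intronless copies by descending
# identity, and the diverged paralog, which keeps introns and an intact
# reading frame and is therefore not called a pseudogene.
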