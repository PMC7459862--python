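"""Which taxa and phenotype groups does a primer set cover?

Given lineage-annotated sequences and the ids a primer pair amplifies, the
breakdown reports per-taxon totals and covered fractions; a taxon ->
phenotype table adds oxygen-requirement and gram-type summaries.
"""

from kmerprimer import (
    PhenotypeMap,
    SequenceRecord,
    breakdown_by_phenotype,
    breakdown_by_rank,
)

db = []
for i in range(20):
    phylum = "Proteobacteria" if i < 14 else "Firmicutes"
    genus = "Escherichia" if i < 14 else "Bacillus"
    db.append(
        SequenceRecord(f"s{i}", "", "ACGT", lineage=["Bacteria", phylum, genus])
    )

# suppose the primer pair amplified 12 of 14 Proteobacteria and 1 Firmicutes
covered = {f"s{i}" for i in range(12)} | {"s19"}

bd = breakdown_by_rank(db, covered, rank="phylum")
print("phylum\tn_total\tn_covered\tpct")
for taxon, n, c, pct in bd.rows:
    print(f"{taxon}\t{n}\t{c}\t{pct:.2f}")

phenomap = PhenotypeMap(
    {
        "Escherichia": ("facultative_anaerobic", "negative"),
        "Bacillus": ("aerobic", "positive"),
    }
)
print("\noxygen class\tn_total\tn_covered\tpct")
for cls, n, c, pct in breakdown_by_phenotype(db, covered, phenomap, "oxygen").rows:
    print(f"{cls}\t{n}\t{c}\t{pct:.2f}")

# Proteobacteria are covered at 85.71% (12/14), Firmicutes at 16.67%; the
# phenotype view maps the same counts onto oxygen-requirement classes.
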