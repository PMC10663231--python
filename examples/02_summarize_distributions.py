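"""Distribution tables: product classes, mechanism shares, family content.

Reproduces the survey-style summaries: which product classes carry at
least one HK or TF, what fraction of HKs sit in two-component systems,
and which Pfam families dominate each mechanism context.
"""

import tempfile
from pathlib import Path

from regmech import (
    MetadataTable,
    SimConfig,
    assemble_architectures,
    bgc_class_distribution,
    classify_bgcs,
    family_contribution,
    filter_complete,
    filter_hits,
    mechanism_composition,
    read_genbank_dir,
    read_hits_table,
    regulator_census,
    simulate_bgc_set,
)

workdir = Path(tempfile.mkdtemp())
result = simulate_bgc_set(SimConfig(n_bgcs=120, seed=4), workdir)
bgcs = filter_complete(
    read_genbank_dir(workdir, MetadataTable.read(result.metadata_path))
)
architectures, _ = assemble_architectures(
    filter_hits(read_hits_table(result.hits_path))
)
annotations, _pairs = classify_bgcs(bgcs, architectures)

print("== census (overall row) ==")
print(regulator_census(bgcs, annotations).set_index("group").loc["overall"])

print("\n== mechanism composition (percent of each role population) ==")
comp = mechanism_composition(annotations, {b.bgc_id: b.source for b in bgcs})
print(comp.table[comp.table.group == "overall"].to_string(index=False))

print("\n== product classes of BGCs with >=1 HK ==")
dist = bgc_class_distribution(bgcs, annotations, "HK")
print(dist.table[dist.table.group == "overall"].to_string(index=False))

print("\n== phospho-acceptor families among TCS HKs ==")
fam = family_contribution(annotations, architectures, "TCS_HK")
print(fam.table.to_string(index=False))
# Percentages are per source group (and overall); family percentages use
# proteins as denominator, so multi-family proteins count once per family.
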