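"""Haplotype-table I/O, analysis-panel derivation and haplogroup frequencies.

Parses a small inline haplotype table (one row per individual), derives the
15-locus analysis panel from a 17-locus Yfiler-style panel (dropping the
multicopy DYS385a/b pair and scoring DYS389II minus DYS389I), and tabulates
haplogroup carrier frequencies.
"""

import io

import pandas as pd

from ystrpop import (DEFAULT_PANEL_RULES, YFILER_17, derive_analysis_panel,
                     haplogroup_frequency, read_haplotype_table)

table = """population\tgroup\tDYS19\tDYS390\tDYS391
roma_a\tfocal\t15\t22\t10
roma_a\tfocal\t15\t22\t10
roma_a\tfocal\t15\t23\t10
india_x\tsource\t16\t22\t11
india_x\tsource\t14\t21\t10
"""

dataset = read_haplotype_table(io.StringIO(table))
for pop in dataset.populations:
    print(f"{pop.name}: n={pop.n}, distinct haplotypes={pop.h}, group={pop.group}")

panel15 = derive_analysis_panel(YFILER_17, DEFAULT_PANEL_RULES)
print(f"\nYfiler panel: {YFILER_17.L} loci -> analysis panel: {panel15.L} loci")
print("dropped:", sorted(set(YFILER_17.names) - set(panel15.names)))

freqs = haplogroup_frequency(pd.DataFrame({
    "population": ["south", "northwest", "northeast"],
    "carriers": [20, 9, 1],
    "total": [100, 120, 500],
}))
print("\nhaplogroup carrier frequencies:")
print(freqs.to_string(index=False))
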