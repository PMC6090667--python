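"""Simulate a small-RNA library with known ground truth.

Reads follow the layout [4-nt barcode][8-nt UMI][insert][3' adapter],
50 bp single-end; PCR bias and adapter dimers are injected on purpose so
downstream correction has something to correct.
"""

from collections import Counter

from srnakit.simulate import LibraryLayout, SimConfig, make_population, simulate_library

config = SimConfig(seed=7, pcr_cycles=10, n_reads=5000, dimer_fraction=0.01)
population = make_population(
    config, class_mix={"miRNA": 0.6, "p21U": 0.2, "primary_siRNA": 0.2}, n_species=100
)
print("species classes:", dict(Counter(p.species_class for p in population)))

layout = LibraryLayout(barcode="ACGT")
library = simulate_library(population, layout, config)
name, seq = library.reads[0]
print(f"first read ({len(seq)} bp): {seq}")
print(f"  barcode={seq[:4]} umi={seq[4:12]} then insert + adapter")

top = sorted(library.truth, key=lambda t: -t.ligated_count)[:3]
print("most abundant species (truth):")
for t in top:
    print(
        f"  {t.seq_id}: {t.true_count} molecules, {t.ligated_count} ligated,"
        f" {t.distinct_umis} distinct UMIs"
    )
# ligated < true_count reflects ligation bias; distinct_umis < ligated
# would indicate UMI collisions (rare at these depths with 8-nt UMIs).
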