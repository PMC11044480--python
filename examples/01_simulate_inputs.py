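"""Generate a complete synthetic mobilome-seq input set with ground truth.

Builds a 400 kb genome with two planted LTR retrotransposon families,
eccDNA concatemer reads for treatment and control, WGS reads with an
introgressed segment and TE insertions, and prints what was planted.
"""

from mobilome.simulate import (SimConfig, simulate_eccdna_reads,
                               simulate_reference, simulate_wgs_reads)

cfg = SimConfig(seed=1, chrom_lengths=(400_000,), reads_per_condition=100,
                wgs_depth=5.0, introgression=("chr1", 50_000, 200_000, 20.0))
genome, elements, truth = simulate_reference(cfg)
ecc = simulate_eccdna_reads(cfg, truth, "treatment")
wgs = simulate_wgs_reads(cfg, truth, genome)

print(f"genome: {sum(len(s) for s in genome.values()):,} bp, "
      f"{len(elements)} planted elements in "
      f"{len({e.family for e in elements})} families")
for e in elements:
    tag = " (active)" if e.id in truth.active_elements else ""
    print(f"  {e.id}: {e.chrom}:{e.start}-{e.end} {e.family}"
          f" LTRs {e.ltr5}/{e.ltr3}{tag}")
print(f"eccDNA treatment reads: {len(ecc)}; WGS reads: {len(wgs)}; "
      f"planted SNPs: {len(truth.snps)}; "
      f"planted insertions: {[i['position'] for i in truth.insertion_sites]}")
# Active elements are the ones the differential test should flag; the
# insertion positions and SNPs are the WGS stage's ground truth.
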