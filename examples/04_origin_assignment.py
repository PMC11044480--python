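"""Trace an active element to its genome of origin by LTR identity.

The eccDNA consensus LTR is searched against a panel of relative-species
assemblies; the genome holding the closest copy (here planted at 2%
divergence) is called the origin when identity clears 96% with a >= 1
point margin.
"""

from mobilome.simulate import SimConfig, simulate_panel, simulate_reference
from mobilome.structure import assign_origin

cfg = SimConfig(seed=4, chrom_lengths=(400_000,))
genome, elements, truth = simulate_reference(cfg)
panel = simulate_panel(truth, cfg)  # panel_A/B/C at 2% / 8% / 20%

eid = truth.active_elements[0]
elem = next(e for e in elements if e.id == eid)
ltr = truth.element_seqs[eid][elem.ltr5[0]:elem.ltr5[1]]

call = assign_origin(ltr, panel)
print(f"query: {eid} 5' LTR ({len(ltr)} bp)")
for name, (ident, locus) in sorted(call.per_genome.items()):
    print(f"  {name}: best identity {ident:5.2f}% at {locus}")
print(f"assigned origin: {call.assigned} (margin {call.margin:.2f} points)")
# panel_A carries the least-diverged copy, so the LTR is assigned there —
# the synthetic analogue of tracing an introgressed element to a wild
# relative's genome.
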