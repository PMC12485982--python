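"""Simulate a PRO-cap dataset and classify its regulatory elements.

Generates strand-specific 5'/3'-end signal for 12 samples over 4 tissues,
calls peaks on the pooled 5' signal, pairs opposite-strand peaks within
300 bp into divergent elements, and annotates proximity (±500 bp of a
gene TSS) and genomic context.
"""

from procap_atlas import (
    TruthConfig,
    annotate_context,
    annotate_proximity,
    naive_peak_call,
    pair_divergent,
    pool_tissue_signal,
    simulate_dataset,
)

ds = simulate_dataset(TruthConfig(seed=0))
print(f"simulated {len(ds.design)} samples, {len(ds.truth)} planted elements")

pooled = pool_tissue_signal(list(ds.tracks5.values()))
peaks = naive_peak_call(pooled, min_count=20, window=30)
elements = pair_divergent(
    [p for p in peaks if p.interval.strand == "+"],
    [p for p in peaks if p.interval.strand == "-"],
    max_gap=300,
)
elements = annotate_context(annotate_proximity(elements, ds.genes), ds.genes)

n_div = sum(e.directionality == "divergent" for e in elements)
n_prox = sum(e.proximity == "proximal" for e in elements)
print(f"called {len(elements)} elements: {n_div} divergent, "
      f"{len(elements) - n_div} unidirectional; {n_prox} proximal")
print("first three calls:")
for e in elements[:3]:
    print(f"  {e.element_id}: {e.directionality}, {e.proximity}, {e.context}")
# A divergent call means paired initiation on both strands within 300 bp —
# the signature of an active enhancer or promoter; proximal elements sit at
# annotated gene TSSs, distal ones are candidate enhancers.
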