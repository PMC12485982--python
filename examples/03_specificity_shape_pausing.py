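"""Tissue specificity, initiation shape, and pause-distance classes.

Scores every element's tissue restriction (entropy-based S in [0, 1]),
classifies divergent elements as peaked/broad per strand by shape index,
and summarizes single-molecule pause distances into early/intermediate/
late classes.
"""

import pandas as pd

from procap_atlas import (
    ReadPairTable,
    TissueDesign,
    TruthConfig,
    build_count_matrix,
    classify_pausing,
    normalize,
    pause_distances,
    pool_tissue_signal,
    score_elements,
    simulate_dataset,
    size_factors,
    specificity_scores,
)

ds = simulate_dataset(TruthConfig(seed=0))
design = TissueDesign.from_frame(ds.design)
counts = build_count_matrix(ds.tracks5, ds.elements)
norm = normalize(counts, size_factors(counts))

res = specificity_scores(norm.scaled, design)
print("specificity score S (0 = ubiquitous, 1 = single-tissue):")
print(res.score.describe().round(3).to_string())
top = res.score.idxmax()
print(f"most specific element: {top} S={res.score[top]:.3f} "
      f"(planted activity: { {k: round(v) for k, v in next(t for t in ds.truth if t.element_id == top).activity.items()} })")

pooled = pool_tissue_signal([ds.tracks5[s] for s in design.samples_of("liver")])
scored, filtered = score_elements(pooled, ds.elements, min_reads=50)
cats = pd.Series([c.category for _, _, c in scored]).value_counts()
print(f"\nshape categories in liver ({len(scored)} scored, {len(filtered)} under "
      f"the 50-read filter): {cats.to_dict()}")
# P (peaked) strands have SI > -1.5: initiation focused on few bases, the
# TATA-like architecture; B (broad) strands spread initiation widely.

pairs = ReadPairTable(pd.concat([ds.pairs[s].df for s in ds.design["sample_id"]],
                                ignore_index=True))
dists, tally = pause_distances(pairs, ds.elements)
labels = classify_pausing(dists)
med = pd.Series({e: d.median for e, d in dists.items()})
print(f"\npause distances over {tally['assigned']} assigned reads:")
for cls in ("early", "intermediate", "late"):
    els = [e for e, l in labels.items() if l == cls]
    detail = f"median of medians {med[els].median():.0f} bp" if els else "empty"
    print(f"  {cls}: {len(els)} elements, {detail}")
# Pause distance is the per-molecule 5'-to-3' offset: how far RNAPII
# traveled before pausing. Tertile cuts fall at the 1/3 and 2/3 quantiles
# of element medians; when a planted regime (25/50/90 bp) holds more than
# a third of the elements, a boundary lands inside that cluster and a
# class can come out empty — with continuous real-tissue medians the
# classes split evenly.
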