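"""Connectivity-map style screen: locate an up/down disease signature in
drug-induced gene rankings; negative scores mark signature-reversing drugs."""

import spongenet as sn
from spongenet.connectivity import QuerySignature, results_to_frame, screen_drugs

genes = [f"gene_{i:03d}" for i in range(300)]
up, down = genes[:25], genes[25:50]          # disease signature

# drug x gene rank matrix with one planted reversing drug, 2 instances each
ranks = sn.generate_drug_ranks(up, down, genes, n_drugs=15, n_reversing=1,
                               n_instances=2, seed=7)
results = screen_drugs(QuerySignature(set(up), set(down)), ranks,
                       n_permutations=1000, seed=7)

table = results_to_frame(results)
print(table.head(5).round(3).to_string(index=False))
top = results[0]
print(f"\ntop hit: {top.drug} (enrichment {top.enrichment_score:.3f}, "
      f"mean over {top.n_instances} instances {top.mean_score:.3f}, "
      f"p = {top.p_value:.4f})")
# A score near -1 means the drug pushes the signature's up-genes to the
# bottom of its induced ranking and the down-genes to the top — the
# expression-reversal pattern drug repositioning looks for.
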