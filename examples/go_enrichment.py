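"""GO-term enrichment of a gene set with Fisher's exact test.

Builds a reference of 200 genes where one term ("GO:0003677", DNA binding)
is concentrated in the test set, and tests every term for
overrepresentation against the remaining reference genes.
"""

import numpy as np

from wgdpairs.enrichment import enrichment_to_frame, fisher_enrichment

rng = np.random.default_rng(3)
terms = [f"GO:{i:07d}" for i in range(1, 21)]
genes = [f"g{i:03d}" for i in range(200)]
annotations = {
    g: {terms[j] for j in rng.choice(20, size=3, replace=False)}
    for g in genes
}
test = set(genes[:40])
for g in list(test)[:25]:  # concentrate DNA binding in the test set
    annotations[g] = annotations[g] | {"GO:0003677"}
for g in genes[40:50]:
    annotations[g] = annotations[g] | {"GO:0003677"}

results = fisher_enrichment(test, set(genes), annotations)
df = enrichment_to_frame(results).sort_values("adjusted_p")
print(df.head(5).to_string(index=False))
print("overrepresented terms:",
      df.loc[df["overrepresented"], "term"].tolist())

# Only the planted term should survive the BH correction at adjusted
# p <= 0.05; the background terms are assigned independently of the set.
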