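"""t-SNE scatter of the gene representations.

Colors genes by their dominant path-frequency label: good-dominant
(blue), poor-dominant (red), equal (yellow), never walked (green).
The typical picture is a large central cloud of untrained vectors with
two separated trained groups.
"""

import g2vec as gv
from g2vec.plotting import plot_embeddings
from g2vec.walker import path_frequencies

data, _, edges, _ = gv.simulate_cohort(gv.SyntheticCohortConfig(seed=11))
sel = gv.select_markers(data, edges, gv.PipelineConfig(), seed=3)

coords = plot_embeddings(sel.embeddings, sel.frequencies,
                         "embedding_scatter.png", seed=0)
print(f"wrote embedding_scatter.png ({coords.shape[0]} genes projected to 2-D)")
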