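"""Compare polyprotein disorder scored on the intact precursor versus
pooled over its cleaved mature peptides.

The two views differ only near cleavage boundaries, so the gap is
bounded by 100 * n_peptides * (window - 1) / length; with a window of 1
they agree exactly.
"""

import numpy as np

from virodisorder import PredictorSpec
from virodisorder.disorder import polyprotein_disorder_two_ways

rng = np.random.default_rng(3)
parent = "".join(rng.choice(list("EPKSQWFYILM"), size=600))
spans = [(0, 180), (180, 340), (340, 600)]  # three mature peptides

for window in (1, 25):
    spec = PredictorSpec(window=window)
    d_whole, d_cleaved = polyprotein_disorder_two_ways(parent, spans, spec)
    bound = 100.0 * len(spans) * (window - 1) / len(parent)
    print(f"window {window:>2}: whole {d_whole:6.2f}%  cleaved {d_cleaved:6.2f}%  "
          f"|diff| {abs(d_whole - d_cleaved):5.2f}  bound {bound:5.2f}")
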