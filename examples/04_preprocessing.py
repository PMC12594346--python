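"""Prepare raw RNA-seq counts and survival metadata for the pipeline.

Three steps: (1) drop weakly expressed features (mRNAs with >25% of
samples under 5 counts, miRNAs with >25% under 1 count), (2) transform
counts to log2(x+1), and (3) turn survival times into a balanced
binary phenotype — the 75% shortest-surviving uncensored patients form
the short-survival class, topped up on the long side by censored
patients whose follow-up exceeds every short-class survival time.
"""

import numpy as np
import pandas as pd

from coremir.synthetic import (
    SurvivalTable,
    assign_survival_classes,
    filter_low_counts,
    log_normalize,
)

rng = np.random.default_rng(0)
n = 40
counts = pd.DataFrame({
    "hsa-miR-001": rng.poisson(30, n),
    "hsa-miR-002": rng.poisson(0.3, n),     # mostly zero: dropped
    "GENE0001": rng.poisson(200, n),
    "GENE0002": rng.poisson(2, n),          # mostly under 5: dropped
})
roles = pd.Series({c: ("mirna" if c.startswith("hsa") else "mrna")
                   for c in counts.columns})
kept, dropped = filter_low_counts(counts, roles)
print(f"kept {list(kept.columns)}; dropped {dropped}")

logged = log_normalize(kept)
print(f"log2(x+1) range: {logged.min().min():.2f} .. {logged.max().max():.2f}")

survival = SurvivalTable(
    sample_ids=[f"P{i:02d}" for i in range(n)],
    times=np.round(rng.exponential(900, n)),
    censored=rng.random(n) < 0.4,
)
result = assign_survival_classes(survival)
n0 = int((result.classes == 0).sum())
n1 = int((result.classes == 1).sum())
print(f"survival classes: short={n0}, long={n1}, "
      f"excluded={len(result.excluded)}, balanced={result.balanced}")
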