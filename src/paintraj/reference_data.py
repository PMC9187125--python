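"""Published summary tables from the motivating registry cohort (N = 2106).

The patient-level registry data are not publicly deposited; these printed
per-cluster counts are the inputs for worked examples that recompute simple
published quantities exactly (a chi-square test of independence, an
unadjusted odds ratio).
"""

import pandas as pd

#: Sex by trajectory cluster (clusters 1-4).
SEX_BY_CLUSTER = pd.DataFrame(
    {"cluster_1": [313, 229], "cluster_2": [431, 322],
     "cluster_3": [434, 262], "cluster_4": [59, 56]},
    index=["female", "male"],
)

#: Clinically meaningful pain (NRS >= 3) at 30 days, by cluster:
#: (n with meaningful pain, cluster size).
MEANINGFUL_PAIN_30D_BY_CLUSTER = {
    1: (145, 542),
    2: (156, 753),
    3: (158, 696),
    4: (16, 115),
}

#: Published cluster sizes.
CLUSTER_SIZES = (542, 753, 696, 115)
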