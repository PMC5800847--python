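"""Comparative-Ct (2^-ddCt) expression fold-changes from a qPCR Ct table.

Triplicate cycle thresholds are averaged per sample and gene, normalized
to a reference gene within each sample, and expressed relative to the
control group's mean.
"""

import pandas as pd

from songlearn import delta_delta_ct

ct = pd.DataFrame([
    # sample, group, gene, ct  (triplicates)
    *[("t1", "treated", "foxp2", v) for v in (20.0, 20.1, 19.9)],
    *[("t1", "treated", "gapdh", v) for v in (18.0, 18.0, 18.0)],
    *[("t2", "treated", "foxp2", v) for v in (20.4, 20.5, 20.3)],
    *[("t2", "treated", "gapdh", v) for v in (18.2, 18.1, 18.3)],
    *[("c1", "control", "foxp2", v) for v in (22.0, 22.1, 21.9)],
    *[("c1", "control", "gapdh", v) for v in (18.0, 18.0, 18.0)],
    *[("c2", "control", "foxp2", v) for v in (21.8, 22.0, 22.2)],
    *[("c2", "control", "gapdh", v) for v in (17.9, 18.0, 18.1)],
], columns=["sample", "group", "gene", "ct"])

result = delta_delta_ct(ct, target_genes=["foxp2"], reference_gene="gapdh",
                        control_group="control")
print(result.per_sample[["sample", "group", "mean_ct", "dct", "ddct", "fold"]]
      .round(3).to_string(index=False))
print()
print(result.group_summary.round(3).to_string(index=False))

# fold ~4 in the treated samples: the target sits ~2 cycles earlier relative
# to the reference than in controls, i.e. ~2^2 more transcript.
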