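"""Full pipeline on a simulated six-condition metabolic-inhibitor study.

Simulates control + five inhibitor conditions (N = 4 each, pooled QCs
every six injections, 20% per-sample preparation scatter), extracts and
normalizes the data, and runs PCA plus per-condition Welch/BH-FDR
differential statistics.
"""

import numpy as np

from ccmscan import RunSpec, run_inhibitor_study

res = run_inhibitor_study(seed=1, spec=RunSpec(seed=1))

meta = res.raw.sample_meta
print(f"injections: {len(meta)} ({(meta.role == 'study').sum()} study, "
      f"{(meta.role == 'QC').sum()} pooled QC)")
print(f"IS stability screen: {int(res.stability['passed'].sum())}/"
      f"{len(res.stability)} below the 22% CV gate "
      f"(CVs track the injected 20% prep scatter)")
print(f"pooled-QC precision after normalization: median CV "
      f"{res.qc['cv_pct'].median():.2f}%")
print(f"PCA explained variance: PC1 {100 * res.pca_fraction[0]:.0f}%, "
      f"PC2 {100 * res.pca_fraction[1]:.0f}%")

print("\ntop differential metabolites per condition (adjusted p < 0.05):")
for name, top in res.top10.items():
    print(f"  {name:10s} {len(top):2d} hits; strongest: "
          + "; ".join(top.index[:3]))
# Each inhibitor's perturbed metabolites surface with the expected
# direction: e.g. the succinate-dehydrogenase block accumulates
# succinate while fumarate and glutathione fall.
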