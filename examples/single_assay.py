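"""Simulate one prothrombin-time (PT) assay.

Loads the packaged Hockin-Mann tissue-factor pathway model, adds a 5 nM
tissue-factor bolus to an average individual's plasma, and integrates
the cascade until free thrombin (activated factor II) reaches the 20 nM
clot threshold.  The printed PT is this model's analog of the laboratory
prothrombin time; the milestones show the explosive character of
thrombin generation once the cascade ignites.
"""

import numpy as np

from coagsim import AssayConditions, load_network, simulate_clotting

network = load_network()
conditions = AssayConditions()  # 5 nM TF, 20 nM thrombin threshold
result = simulate_clotting(network, None, conditions)

print(f"prothrombin time: {result.prothrombin_time_s:.2f} s")
for level in (0.1, 1.0, 5.0, 10.0, 20.0):
    i = int(np.searchsorted(result.readout, level))
    if i < result.times.size:
        print(f"  thrombin reaches {level:5.1f} nM at t = {result.times[i]:6.2f} s")
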