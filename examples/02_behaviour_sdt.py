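"""Signal-detection analysis of simulated human/non-human judgements.

Generates behavioural trials for three conditions with known sensitivity
(android d'=2.27, robot d'=4.0) and log-normal reaction times, then runs
the d'/RT analysis and prints the group summary.
"""

import numpy as np

from erpmvpa import group_sdt, sdt_summary, simulate_behaviour
from erpmvpa.simulate import GeneratorConfig

cfg = GeneratorConfig(n_participants=20, n_trials_per_condition=180, seed=2)
trials = simulate_behaviour(cfg)

per_participant = sdt_summary(trials, human_label="human")
group = group_sdt(per_participant, n_boot=2000, rng=np.random.default_rng(2))
print(group.round(3).to_string(index=False))
# dprime recovers the configured sensitivities (android 2.27, robot 4.0)
# within sampling error; rt_geomean the configured log-normal medians
# (~800/688 ms).  Capping at +/-5 keeps perfect hit rates finite; at small
# trial counts it biases very large d' upward (see docs/methods.md).
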