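"""Timepoint-wise multivariate decoding with sub-averaged training exemplars.

Decodes human vs android from the full 32-channel pattern at every 4th
timepoint: per permutation, 4 training exemplars per class are formed by
averaging random disjoint 20% subsets of trials, a linear SVM is trained on
them and tested on the held-out trials.  Group evidence against 50% chance
is a one-sample JZS Bayes factor at each timepoint.

Runs in about a minute; increase n_permutations to 1000 and time_decim to 1
for a full-resolution analysis.
"""

import numpy as np

from erpmvpa import simulate_epochs
from erpmvpa.decoding import DecoderConfig, decode_timecourse
from erpmvpa.preprocess import bandpass, baseline_correct
from erpmvpa.simulate import GeneratorConfig

pair = ("human", "android")
cfg = GeneratorConfig(n_participants=12, n_trials_per_condition=30, seed=3)
cohort = [baseline_correct(bandpass(es)) for es in simulate_epochs(cfg, pair)]

dec = DecoderConfig(n_permutations=200, seed=3)
result = decode_timecourse(cohort, pair, dec, time_decim=4)

for lo, hi, label in [(-200, 0, "pre-stimulus"), (100, 200, "early window"),
                      (580, 620, "late window")]:
    m = (result.times >= lo) & (result.times <= hi)
    acc = 100 * result.group_mean[m].mean()
    bfmax = np.nanmax(result.bf_vs_chance.bf10[m])
    print(f"{label:>13} ({lo:>4}..{hi:>4} ms): "
          f"mean accuracy {acc:5.1f}%, max BF10 {bfmax:10.3g}")
# Accuracy sits at ~50% pre-stimulus and rises inside the two injected
# effect windows, where BF10 >> 30 indicates very strong evidence of
# condition-specific information in the scalp pattern.
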