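"""Consonant confusions and Miller-Nicely information transfer.

Simulates 20 presentations of each of the 60 vowel-consonant-vowel
tokens through a feature channel that transmits voicing with p = 0.96,
manner with p = 0.95 and place of articulation with p = 0.75, then
recovers per-feature relative information transfer from the confusion
matrix.  Place, carried by spectral detail that vocoding destroys, is
transmitted far worse than voice and manner, which ride on the temporal
envelope.
"""

import numpy as np

from tevoc import build_confusion, collapse_to_feature, load_feature_map, percent_correct, relative_it
from tevoc.observer import FeatureTransmission, simulate_vcv_trials

fmap = load_feature_map()
ft = FeatureTransmission(t_voice=0.96, t_manner=0.95, t_place=0.75)
trials = simulate_vcv_trials(ft, fmap, n_per_token=20, rng=np.random.default_rng(1))

print(f"{len(trials)} trials, {percent_correct(trials):.1f} % consonants correct")
cm = build_confusion(trials)
print("feature | transmission p | IT (bits) | input entropy | relative IT")
for feat, t in (("voice", 0.96), ("manner", 0.95), ("place", 0.75)):
    res = relative_it(collapse_to_feature(cm, fmap, feat))
    print(f" {feat:7s}|      {t:.2f}      |   {res.it_bits:.3f}   |     {res.input_entropy_bits:.3f}     "
          f"|   {res.relative_it:5.1f} %")
print("Relative IT normalises by input entropy, making the three features comparable")
print("despite their different numbers of categories and category priors.")
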