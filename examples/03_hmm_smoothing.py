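"""Hidden-Markov time smoothing of forest predictions.

Shows the core idea on a tiny model: a single-epoch "blip" of a different
behaviour inside a stable bout is decoded away by Viterbi, because the
transition matrix makes rapid switching improbable.  Then demonstrates
transition estimation from label sequences.
"""

import numpy as np

from wristml import hmm as H
from wristml.forest import ClassScheme

scheme = ClassScheme(("sleep", "walking"))
model = H.HmmModel(
    scheme,
    initial=np.array([0.5, 0.5]),
    transition=np.array([[0.99, 0.01], [0.01, 0.99]]),  # sticky bouts
    emission=np.array([[0.8, 0.2], [0.2, 0.8]]),        # noisy classifier
)

obs = np.array([0, 0, 0, 1, 0, 0, 0])  # a lone "walking" inside sleep
decoded = H.viterbi(model, obs)
print("observed :", [scheme.classes[i] for i in obs])
print("decoded  :", [scheme.classes[i] for i in decoded])

marg = H.forward_backward(model, obs)
print("\nP(walking | observations) per epoch:",
      np.round(marg[:, 1], 3).tolist())

# The decoded path removes the blip; the marginal at the blip epoch stays
# elevated but below 0.5 — exactly the soft information MET prediction uses.

seqs = [np.array([0, 0, 0, 1, 1]), np.array([1, 1, 0])]
tm = H.estimate_transitions(seqs, k=2)
print("\nempirical transition matrix (rows sum to 1):")
print(np.round(tm.probs, 3))
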