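"""From raw signal to behaviour probabilities.

Extracts the 126-feature representation of each 30-s epoch, trains a
balanced random forest, and prints the out-of-bag emission matrix — the
forest's own estimate of p(predicted class | true class), which doubles as
the HMM emission distribution.
"""

import numpy as np

from wristml import forest as rf, simulate as sim
from wristml.features import feature_matrix
from wristml.signal import epoch_array

chain = sim.demo_chain()
lrec = sim.simulate_recording(
    sim.simulate_label_sequence(chain, 480, seed=3),  # 4 h
    sim.default_profiles(),
    seed=3,
)
X, valid = feature_matrix(epoch_array(lrec.recording))
print(f"feature matrix: {X.shape[0]} epochs x {X.shape[1]} features")

scheme = rf.ClassScheme(chain.classes)
model = rf.train_balanced_forest(
    X, lrec.epoch_labels, rf.TrainingConfig(n_trees=50, seed=3), scheme
)
print(f"forest: {model.n_trees} trees, balanced bags of "
      f"{model.n_rare} epochs per class")

emission = rf.oob_emission_matrix(model, X, lrec.epoch_labels)
print("\nOOB emission matrix p(predicted | true):")
print("            " + "  ".join(f"{c:>10s}" for c in scheme.classes))
for i, cls in enumerate(scheme.classes):
    row = "  ".join(f"{p:10.3f}" for p in emission.probs[i])
    print(f"{cls:>10s}  {row}")

# Strong diagonals mean the forest rarely confuses that behaviour;
# off-diagonal mass (typically sit/stand vs quiet movement) is exactly the
# noise the HMM smoothing step is built to repair.
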