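"""Non-wear handling and marginal-weighted MET prediction.

Injects a non-wear episode into a recording, detects it from the raw
signal, imputes the gap from matching time-of-day data, and converts
behaviour marginals into MET-hours/day.
"""

import numpy as np

from wristml import met as M, simulate as sim, wear

# -- non-wear detection on a recording with an injected 90-min episode
cohort = sim.simulate_cohort(1, 30.0, nonwear_rate=0.8, seed=12)
lrec = cohort[0]
mask = wear.detect_nonwear(lrec.recording)
print(f"epochs: {mask.n_epochs}, non-worn detected: {int((~mask.worn).sum())}, "
      f"truth: {int(lrec.nonwear_truth.sum())}")
for start, stop, reason in mask.episodes:
    print(f"  episode epochs [{start}, {stop}) - {reason}")

slot = wear.epoch_slot_index(lrec.recording, mask.n_epochs)
met_truth = lrec.true_met()
imputed, was_imputed, missing = wear.impute_nonwear(met_truth, mask, slot)
print(f"imputed epochs: {int(was_imputed.sum())}, "
      f"no-donor epochs: {int(missing.sum())}")

# -- MET from marginal state probabilities
scheme = M.class_met_scores(
    [("sitting", "desk work", 1.3), ("sitting", "reading", 1.5),
     ("walking", "stroll", 3.5), ("sports", "squash", 8.0)],
    classes=("sitting", "walking", "sports"),
)
print("\nrepresentative METs:", dict(zip(scheme.classes, scheme.values)))

marginals = np.array([
    [1.0, 0.0, 0.0],   # certainly sitting        -> 1.4
    [0.5, 0.5, 0.0],   # sitting-or-walking       -> 2.45
    [0.0, 0.2, 0.8],   # probably sports          -> 7.1
])
series = M.predict_met(marginals, scheme, day_index=np.zeros(3, dtype=int))
print("epoch MET:", np.round(series.epoch_met, 2).tolist())
print("MET-hours for these 3 epochs:", round(float(series.met_hours_per_day[0]), 4))

# Epoch MET is a convex combination of class METs, so uncertainty between a
# low- and a high-energy behaviour lands between their values instead of
# flipping; a day of such epochs sums to MET-hours/day.
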