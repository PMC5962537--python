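# Examples

Short narrative scripts, one per capability; each builds or simulates a
small input, runs the method and prints what it computes.

| script | what it shows |
| --- | --- |
| `01_simulate_cohort.py` | synthetic labelled cohorts: Markov behaviour labels, per-epoch METs, injected non-wear |
| `02_features_and_forest.py` | 126-feature epochs, balanced-forest training, the out-of-bag emission matrix |
| `03_hmm_smoothing.py` | Viterbi blip correction, forward–backward marginals, empirical transitions |
| `04_wear_and_met.py` | non-wear detection and time-of-day imputation; marginal-weighted MET |
| `05_loso_evaluation.py` | leave-one-subject-out evaluation: kappa raw vs smoothed, confusion, MET error |

Run any of them from the repository root, e.g.

```bash
python examples/05_loso_evaluation.py
```

All scripts finish in seconds except `05`, which takes about a minute.
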