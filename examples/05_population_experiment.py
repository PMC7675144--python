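"""A miniature population experiment: generate, fit, evaluate, report.

Builds a 6-neuron mixed population (LN / STP / GC ground truths with trial
noise), fits all four architectures to every neuron and prints the
population summary: median prediction correlations per architecture,
responsive/improved counts, and the median equivalence between the STP and
GC fits.  Expect the combined GC+STP model at or near the top and a
between-model equivalence well below 1.

Takes a few minutes on one CPU.
"""

import json

from audenc import ExperimentConfig, FitConfig, run_experiment

config = ExperimentConfig(
    regime="smooth_contrast",
    n_neurons=6,
    n_stimuli=10,
    duration_s=2.0,
    noise_levels=(0.4,),
    fit=FitConfig(max_iter=800),
    n_perm=300,
    seed=0,
)
report = run_experiment(config)

cols = ["true_class", "r_LN", "r_STP", "r_GC", "r_GC+STP",
        "responsive", "improved", "equivalence", "reliability"]
print(report.neurons[cols].round(3).to_string(index=False))
print()
print(json.dumps({k: (round(v, 4) if isinstance(v, float) else v)
                  for k, v in report.summary.items()}, indent=1))
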