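"""Fit the meta-d' model to one simulated session of the dot-numerosity task.

Simulates 136 2-AFC trials (the default two-block design) from an observer
with moderate metacognitive noise, then estimates type-1 and type-2
parameters by maximum likelihood.
"""

from metacog import (ObserverParams, counts_from_trials, fit_metad,
                     generate_design, simulate_observer)

spec, trials = generate_design("perception", seed=1)
params = ObserverParams(sensitivity_scale=0.045,  # d' = 0.045 * |dot difference|
                        criterion=0.1,            # slight "left" response bias
                        meta_noise_sd=0.3)        # confidence noisier than choice
session = simulate_observer(trials, params, seed=2)

fit = fit_metad(counts_from_trials(session, K=6))
print(f"d'                   = {fit.type1.d_prime:.3f}")
print(f"type-1 c             = {fit.type1.c:.3f}")
print(f"meta-d'              = {fit.meta_d:.3f}")
print(f"Mratio (meta-d'/d')  = {fit.m_ratio:.3f}")
print(f"confidence criterion = {fit.confidence_criterion:.3f}")

# d' near 1.5 means reliable first-order discrimination; an Mratio below 1
# quantifies how much of that evidence is lost to the confidence judgement;
# the confidence criterion is the mean distance of the type-2 criteria from
# the type-1 criterion - larger values mean a low-confidence reporting bias.
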