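"""Sample-size planning for a small regression effect (Cohen's f2 = 0.02).

Reproduces the a-priori and post-hoc power calculations for testing one
symptom-dimension coefficient among five predictors (three dimensions plus
age and gender) at alpha = 0.05.
"""

from metacog import PowerSpec, power_for_n, required_n

n80 = required_n(f2=0.02, target_power=0.80)
print(f"n required for 80% power at f2=0.02 : {n80}")

p473 = power_for_n(PowerSpec(f2=0.02, n=473))
print(f"power achieved at n=473             : {100 * p473:.1f}%")

# The first number is the planning target for a replication sample; the
# second is the power retained after data exclusions reduce the sample.
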