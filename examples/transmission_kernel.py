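"""Evaluate the distance-decay transmission kernel and verify it by
Monte-Carlo simulation of single months."""

from agrisk import TransmissionParams, infection_frequency, transmission_probability

params = TransmissionParams()  # p_inf = 0.15, 25% reduction per level

print("Per-month transmission probability p_inf / D^2 x 0.75^level:")
for distance in (1.0, 2.0, 4.0):
    for level in (0, 1, 3):
        p = transmission_probability(distance, level, params)
        print(f"  D={distance:>3}, level={level}: p = {p:.4f}")

freq = infection_frequency(1.0, 0, params, n_replicates=50_000, rng_seed=7)
print(f"\nMonte-Carlo frequency at D=1, level 0 over 50,000 months: {freq:.4f}")
print("-> matches the configured baseline 0.15 up to binomial noise;")
print("   each biosecurity level would retain 75% of that hazard.")
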