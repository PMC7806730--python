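"""Sample sizes needed to detect large effects with the study's design.

For a paired t test the power comes from the noncentral t distribution; for a
correlation both the exact sampling distribution of r and the Fisher-z
approximation are available.
"""

from demgaze import PowerQuery, required_n_correlation, required_n_paired_t

q = PowerQuery(effect_size=0.5, alpha=0.05, power=0.80, one_sided=True)
print(f"paired t, dz = 0.5, one-sided alpha .05, power .80 -> n = {required_n_paired_t(q)}")
print(f"correlation rho = 0.5, exact r distribution      -> n = {required_n_correlation(q, 'exact')}")
print(f"correlation rho = 0.5, Fisher-z approximation    -> n = {required_n_correlation(q, 'fisher-z')}")

small = PowerQuery(effect_size=0.3, one_sided=True)
print(f"a medium effect (rho = 0.3) instead needs n = {required_n_correlation(small, 'exact')}")
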