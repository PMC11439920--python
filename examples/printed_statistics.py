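"""The contrast layer's statistic conversions on their own.

Reproduces the kinds of numbers the reporting layer prints: two-sided
p-values from t statistics, paired and pooled Cohen's d, and the cohort
sensitivity power analysis.
"""

import neuralign as na
from neuralign.stats import SummaryStats

print("two-sided p from t and df:")
for t, df in [(2.362, 36), (2.669, 36), (-0.185, 41)]:
    print(f"  t({df}) = {t:+.3f}  ->  p = {na.two_tailed_p(t, df):.3f}")

print("paired Cohen's d = t / sqrt(n):")
for t, n in [(2.362, 37), (2.669, 37), (-1.916, 42)]:
    print(f"  t = {t:+.3f}, n = {n}  ->  d = {na.cohens_d_from_t(t, n):+.3f}")

a = SummaryStats(mean=7.34, sd=2.32, n=37)
b = SummaryStats(mean=6.03, sd=3.09, n=42)
print(f"pooled-SD Cohen's d for {a.mean}+/-{a.sd} (n={a.n}) vs "
      f"{b.mean}+/-{b.sd} (n={b.n}): {na.cohens_d_pooled(a, b):.2f}")

d = na.sensitivity_power(n=37, alpha=0.05, power=0.80)
print(f"minimal detectable paired d at n=37, alpha=0.05, power=0.80: {d:.2f}")
print()
print("The sensitivity value is the smallest within-subject effect a paired")
print("t-test on 37 subjects detects with 80% power at two-sided alpha 0.05.")
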