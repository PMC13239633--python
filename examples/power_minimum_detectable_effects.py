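"""Minimum detectable effect sizes for the 10 + 10 study design.

Root-finds the effect at which exact noncentral-t power (t tests) or the
bias-corrected Fisher-z power (correlations) reaches 80% at two-sided
alpha = 0.05.
"""

from tractconfound import min_detectable_effect

print("80% power, two-sided alpha 0.05:")
print(f"  between-group Cohen's d (n = 10/group): "
      f"{min_detectable_effect('between_t', 10):.2f}")
print(f"  within-group Cohen's d  (n = 10):       "
      f"{min_detectable_effect('within_t', 10):.2f}")
print(f"  Pearson correlation     (n = 20):       "
      f"{min_detectable_effect('correlation', 20):.2f}")
print("\nSmaller n raises every minimum detectable effect; a 20-participant")
print("study can only resolve large group differences and strong correlations.")
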