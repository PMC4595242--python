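"""Per-cause diagnostic accuracy of verbal autopsy with Wilson intervals.

Uses the study's published 2x2 counts for birth asphyxia (147 true and 41
false positives, 409 true and 29 false negatives over 626 deaths) and prints
the four accuracy statistics with their 95% score intervals, plus the
chi-square test of association between VA and reference diagnoses.
"""
from neoval import ContingencyCounts, chi_square_2x2, diagnostic_accuracy

counts = ContingencyCounts("birth_asphyxia", tp=147, fp=41, tn=409, fn=29)
acc = diagnostic_accuracy(counts)

for name in ("sensitivity", "specificity", "ppv", "npv"):
    point, lo, hi = getattr(acc, name).as_pct()
    print(f"{name:12s} {point:5.1f}%  (95% CI {lo:.1f}-{hi:.1f})")

stat, p = chi_square_2x2(counts)
print(f"\nchi-square = {stat:.1f}, p = {p:.3g}  "
      "(VA and reference diagnoses are strongly associated)")
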