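"""Chi-square goodness of fit of observed ear counts to a 3:1 ratio.

Two F3 ear-count pairs (normal:reversed) are tested against the 3:1
segregation expected for a single recessive locus. A chi2 at or below the
critical value 3.84 (alpha = 0.05, df = 1) means the counts are consistent
with 3:1, supporting a single-gene recessive model.
"""

from bulkscan import chi_square_ratio_test

for observed in [(165, 67), (69, 28)]:
    res = chi_square_ratio_test(observed, ratio=(3, 1))
    print(
        f"{observed[0]}:{observed[1]} vs 3:1 -> chi2 = {res.chi2:.4f} "
        f"(critical {res.critical_value}) -> "
        f"{'consistent' if res.consistent else 'deviates'}"
    )
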