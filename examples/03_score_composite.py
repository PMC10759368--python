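"""Compute the 0-5 clock-plus-recall composite and its color bands.

The clock summary (0-100) maps to 0-2 points (<60 / 60-74 / >=75) and each
delayed-recall word adds one point (0-3). Totals 4-5 are Green (no
indication of impairment), 2-3 Yellow (borderline), 0-1 Red.
"""

import cogscreen as cs

for summary, words in [(82.5, 3), (74.5, 2), (59.9, 1), (40.0, 0)]:
    score = cs.dcr_total(cs.clock_points(summary), cs.recall_points(words))
    flag = "screen-positive" if cs.dcr_screen_positive(score) else "screen-negative"
    print(f"clock summary {summary:5.1f}, {words} words recalled -> "
          f"total {score.total} ({score.band}, {flag})")

print()
for mmse in (30, 28, 27):
    label = "unimpaired" if cs.mmse_screen_negative(mmse) else "impaired"
    print(f"MMSE {mmse} -> screen labels {label} (cutoff 28)")
# A total of <= 3 flags possible impairment; the MMSE rule labels >= 28
# as unimpaired, the conservative cutoff used for comparison.
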