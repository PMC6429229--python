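"""Classification quality indicators from a published confusion table.

Given the confusion counts of a classifier evaluated on 120 compounds
(44 true positives, 61 true negatives, 9 false positives, 6 false
negatives), the indicator suite reports sensitivity, specificity, both
accuracy conventions, predictive values, the Matthews correlation
coefficient and the prediction rate.
"""

from btlqsar import metrics as mx

cc = mx.ConfusionCounts(tp=44, tn=61, fp=9, fn=6, n_total=120)
report = mx.quality_indicators(cc)
for key, value in report.rounded(2).items():
    print(f"{key:>12}: {value:.2f}")

# an abstaining classifier: 75 of 120 compounds predicted
cc_abstain = mx.ConfusionCounts(tp=29, tn=45, fp=1, fn=0, n_total=120)
q = mx.quality_indicators(cc_abstain)
print(f"\nwith abstentions: ACC={q.acc_standard:.2f} at PR={q.pr:.3f} "
      "(accuracy bought by predicting fewer compounds)")
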