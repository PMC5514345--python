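"""Recompute the published classifier results from their confusion matrices.

The study's 200-patient recordings are not deposited, but its best
classifier's confusion matrices are printed; every reported metric derivable
from them is recomputed here by the package's evaluation suite.
"""

import acetowhite as aw
from acetowhite.reference import binary_knn_pla_confusion, multiclass_knn_pla_confusion

b = aw.binary_metrics(binary_knn_pla_confusion())
print("binary 1-NN / discrete PLA (positive = LSIL or HSIL):")
print(f"  sensitivity {aw.percent_round(b.extras['sensitivity'])}%  "
      f"(95% CI {aw.percent_round(b.extras['sensitivity_ci'][0])}-"
      f"{aw.percent_round(b.extras['sensitivity_ci'][1])})")
print(f"  specificity {aw.percent_round(b.extras['specificity'])}%  "
      f"(95% CI {aw.percent_round(b.extras['specificity_ci'][0])}-"
      f"{aw.percent_round(b.extras['specificity_ci'][1])})")
print(f"  accuracy    {aw.percent_round(b.accuracy)}%")
print(f"  MCC {b.extras['mcc']:.3f}   weighted FP rate {b.weighted['fp_rate']:.3f}   "
      f"weighted F-measure {b.weighted['f_measure']:.3f}")

m = aw.multiclass_metrics(multiclass_knn_pla_confusion())
print("\nsix-class 1-NN / discrete PLA, detailed accuracy by class:")
print(f"  {'class':<14} {'tp_rate':>7} {'fp_rate':>7} {'prec':>6} {'F':>6} {'MCC':>7}")
for cls in m.class_list:
    r = m.per_class[cls]
    print(f"  {cls:<14} {r['tp_rate']:7.3f} {r['fp_rate']:7.3f} "
          f"{r['precision']:6.3f} {r['f_measure']:6.3f} {r['mcc']:7.3f}")
w = m.weighted
print(f"  {'weighted avg':<14} {w['tp_rate']:7.3f} {w['fp_rate']:7.3f} "
      f"{w['precision']:6.3f} {w['f_measure']:6.3f} {w['mcc']:7.3f}")
print(f"  overall accuracy {aw.percent_round(m.accuracy)}%")
print(
    "\nOnly the two largest classes (normal, HSIL) are ever predicted: the "
    "classifier collapses the small benign classes into 'normal' and most "
    "LSIL into 'normal' or 'HSIL' - the class-imbalance failure the study "
    "reports."
)
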