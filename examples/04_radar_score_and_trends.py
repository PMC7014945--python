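"""Aggregate performance with the radar-polygon score and trend correlations.

Takes metric records for several runs (here: a published-style series of
multi-class results at 3, 5, 7, 9 and 11 classes), scales the feature-count
and learning-time axes across runs (inverted, so fewer/faster = radius 1),
computes each run's polygon area as a percentage of the maximal area, and
correlates each metric with the number of classes.
"""

from gars import pearson_trend, radar_area, scale_metrics_for_radar

runs = [
    {"classes": 3, "ACC": 0.92, "SEN": 0.89, "SPE": 0.95, "PPV": 0.87,
     "NPV": 0.94, "Time": 59 * 60, "Nfeats": 15},
    {"classes": 5, "ACC": 0.91, "SEN": 0.85, "SPE": 0.96, "PPV": 0.84,
     "NPV": 0.96, "Time": 108 * 60, "Nfeats": 18},
    {"classes": 7, "ACC": 0.89, "SEN": 0.82, "SPE": 0.97, "PPV": 0.78,
     "NPV": 0.97, "Time": 223 * 60, "Nfeats": 18},
    {"classes": 9, "ACC": 0.89, "SEN": 0.82, "SPE": 0.97, "PPV": 0.79,
     "NPV": 0.97, "Time": 409 * 60, "Nfeats": 24},
    {"classes": 11, "ACC": 0.86, "SEN": 0.75, "SPE": 0.97, "PPV": 0.72,
     "NPV": 0.97, "Time": 715 * 60, "Nfeats": 22},
]

radii_rows, axes = scale_metrics_for_radar(runs)
print("radar axes:", axes)
for run, radii in zip(runs, radii_rows):
    score = radar_area(radii)
    print(f"{run['classes']:>2} classes: polygon covers {score.A_percent:.1f}% of the maximal area")

x = [run["classes"] for run in runs]
print("\ncorrelation of each metric with the number of classes:")
for name in ("ACC", "SEN", "SPE", "PPV", "NPV", "Nfeats"):
    r = pearson_trend(x, [run[name] for run in runs])
    print(f"  {name}: r = {r:.2f}")
print("\nAccuracy, sensitivity and PPV decrease as the task gains classes,")
print("while specificity, NPV and the selected-subset size increase.")
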