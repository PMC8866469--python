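"""Cohort-level severity statistics on a simulated case-control study.

Simulates healthy and diseased eyes (30% capillary dropout), then runs
the nonparametric comparison and ROC analysis of each spectrum
parameter.
"""

from icspectrum import SceneConfig
from icspectrum.pipeline import simulate_cohort
from icspectrum.stats import severity_report

scene = SceneConfig(grid_px=384, noise_sd=0.05, transient_rate=0.05)
cohort = simulate_cohort(
    {
        "healthy": {"dropout": 0.0, "grade": "nondiabetic"},
        "diseased": {"dropout": 0.3, "grade": "moderate_npdr"},
    },
    n_per_group=8,
    seed=42,
    scene=scene,
)

report = severity_report(cohort)
for param in ("total_count", "mean_area_mm2", "count_ap_above_0.025"):
    blk = report["parameters"][param]
    med = {g: f"{v[0]:.4g} ({v[1]:.4g}-{v[2]:.4g})" for g, v in blk["by_grade"].items()}
    roc = blk["roc"]["diabetic_vs_nondiabetic"]
    kw = blk["tests"][0]
    print(f"{param}:")
    print(f"  median (IQR) by grade: {med}")
    print(f"  Kruskal-Wallis p = {kw['p_raw']:.2e}; "
          f"AUC = {roc['auc']:.3f} (95% CI {roc['ci95'][0]:.3f}-{roc['ci95'][1]:.3f})")
# AUC near 1 here reflects the clean separation of the synthetic effect
# size; a diseased eye has fewer, larger, smoother intercapillary spaces.
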