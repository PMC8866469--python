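"""Quantify intercapillary spaces on one en-face image.

Runs the four-step chain (normalize, denoise, Phansalkar binarization,
particle morphometry in the central 2 mm circle), excludes the FAZ, and
prints the per-eye spectrum summary.
"""

from icspectrum import SceneConfig
from icspectrum.pipeline import analyze_frames, default_run_config, simulate_eye

scene = SceneConfig(grid_px=512, dropout_rate=0.2, transient_rate=0.1,
                    noise_sd=0.05, rng_seed=11)
sim = simulate_eye(scene)

config = default_run_config(scene.grid_px)   # blur + window scaled to pitch
result = analyze_frames(sim["frames"], config, eye_id="demo", grade="moderate_npdr")

eye = result["spectrum"]
print(f"spaces detected (FAZ excluded): {eye.total_count}")
print(f"mean area:        {eye.mean_area_mm2*1e3:.3f} x10^-3 mm^2")
print(f"mean perimeter:   {eye.mean_perimeter_mm:.3f} mm")
print(f"mean min/max diameter: {eye.mean_min_diameter_mm:.3f} / "
      f"{eye.mean_max_diameter_mm:.3f} mm")
print(f"spaces > 0.03 mm^2:          {eye.counts_above_area[0.03]}")
print(f"spaces with A/P > 0.025:     {eye.count_ap_above}")
print(f"FAZ area:                    {eye.faz_area_mm2:.4f} mm^2")
# Counts fall and sizes grow with capillary dropout -- the morphometric
# signature of nonperfusion; the transient-loss map flags capillaries
# recovered by frame averaging.
print(f"pixels with transient flow-signal loss: {result['transient_map'].sum()}")
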