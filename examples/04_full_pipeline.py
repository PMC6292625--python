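"""Run the full mapping pipeline on a synthetic survey scene.

Generates a country-scale scene with a covariate-driven indicator
(banana-like: environmental gradients plus a spatially structured
residual) and a purely local one (beans-like: no covariate signal, pure
nugget), runs indicator computation -> regression -> residual
geostatistics -> map composition for both plus the FA regression-kriging
path, and prints the per-indicator report.
"""

from famap import PipelineConfig, run_pipeline
from famap.synthetic import SceneConfig, _default_indicators

indicators = _default_indicators()
scene = SceneConfig(n_ea=60, households_per_ea=8, resolution_deg=0.25,
                    indicators={k: indicators[k] for k in ("banana", "beans")})
config = PipelineConfig(scene=scene, indicators=["FA", "banana", "beans"],
                        seed=2, fit_evhr=False)

report = run_pipeline(config)
for row in report.rows:
    print(f"{row['indicator']:>8s}: {row['family']:<6s} "
          f"fit={row['fit_stat']:.3f}  "
          f"nugget-sill ratio={row['nugget_sill_ratio']:.2f}  "
          f"range={row['range_km']:.0f} km  "
          f"structured={row['spatial_structure']}")
print()
print("fit is R2 (FA) or pseudo-R2 (shares); a nugget-sill ratio <= 0.7")
print("flags residual spatial autocorrelation worth interpolating. The")
print("covariate-driven indicator is predictable and spatially structured;")
print("the local one is neither - the contrast the procedure diagnoses.")
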