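"""Wet-assay formulas: NBD quenching, GUV readouts, EM radius, GTPase rate."""

import memflex as mx

# dithionite quenching: only the outer probe half quenched, no permeation
df, _ = mx.make_assay_series("quench", {"outer_fraction": 0.5, "slow_rate": 0.0})
trace = mx.QuenchTrace.from_dataframe(df, triton_time=351.0)
print(f"fast-phase quench plateau: {mx.quench_plateau(trace, 300.0):.1f}% "
      "(50% = impermeable membrane, only external probes quenched)")

# GUV permeability and shrinkage
m = mx.GuvMeasurement(i_in=30.0, i_ex=300.0, a0=80.0, ai=40.0)
print(f"GUV permeability: {mx.guv_permeability(m):.1f}%")
print(f"GUV shrinkage (printed form A0/Ai): {mx.guv_shrinkage(m):.0f}%; "
      f"area consumed: {mx.guv_shrinkage(m, ratio='consumed'):.0f}%")

# apparent radius of an EM profile
print(f"apparent radius of a 1256.6 nm² profile: "
      f"{mx.apparent_radius(1256.64):.1f} nm")

# GTPase turnover from a malachite-green phosphate series
data, truth = mx.make_assay_series("gtpase", {"rate_per_s": 2.0, "noise_uM": 2.0},
                                   seed=3)
series = mx.PhosphateSeries(data["series"]["time_s"], data["series"]["abs_650"],
                            data["standards"], data["dynamin_conc_uM"])
fit = mx.gtpase_rate(series)
print(f"planted rate {truth.assay['rate_per_s']} s⁻¹ -> "
      f"fitted {fit.rate:.2f} s⁻¹ "
      f"({fit.slope_uM_per_s:.3f} µM/s at {series.dynamin_conc} µM enzyme)")
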