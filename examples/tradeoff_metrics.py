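"""Sex-specific nutritional trade-offs: angle theta and hypotenuse.

Fits female and male landscapes with different optima, then expresses their
difference as the signed angle theta between the two optimum vectors
(nutrient balance) and the difference in hypotenuse (total diet quantity),
with bootstrap confidence intervals for the single-sex metrics.
"""

from nutriphylo import (
    LandscapeSpec,
    angle_theta,
    bootstrap_metrics,
    find_peak_region,
    fit_tps,
    hypotenuse,
    simulate_performance_points,
)

# females favour a lower P:C ratio (1:3) than males (1:1.5)
female = simulate_performance_points(LandscapeSpec(peak_p=1.5, peak_c=4.5))
male = simulate_performance_points(LandscapeSpec(peak_p=2.4, peak_c=3.6))

reg_f = find_peak_region(fit_tps(female, smoothing=1e-3), q=0.95)
reg_m = find_peak_region(fit_tps(male, smoothing=1e-3), q=0.95)

theta = angle_theta(reg_f, reg_m)
print(f"theta (female vs male) = {theta:.2f} degrees")
print(f"hypotenuse: female {hypotenuse(reg_f):.2f}, male {hypotenuse(reg_m):.2f}")
# theta < 0: the female optimal P:C ratio is lower than the male one — the
# sexes trade off nutrient balance, not just total intake.

m = bootstrap_metrics(female, B=200, seed=0, smoothing=1e-3)
lo, hi = m.ci["pc_ratio"]
print(f"\nfemale optimal P:C ratio {m.pc_ratio:.3f}, 95% CI [{lo:.3f}, {hi:.3f}]")
lo, hi = m.ci["hypotenuse"]
print(f"female hypotenuse {m.hypotenuse:.2f}, 95% CI [{lo:.2f}, {hi:.2f}]")
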