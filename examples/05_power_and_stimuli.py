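"""Study-planning utilities: sample sizes and the equiluminant color wheel.

Computes the minimum sample sizes for the three designs (one-sample t
tests on bias and a correlation test on individual differences) from the
anticipated effect sizes, and builds the 360-color CIE L*a*b* wheel used
as a continuous-report color space.
"""

from wmbias import (
    cielab_wheel,
    required_n_correlation,
    required_n_one_sample_t,
    wheel_frame,
)

print("minimum n, two-tailed alpha = .05:")
print(f"  one-sample t, d = 0.80, power .80 -> n = "
      f"{required_n_one_sample_t(0.80, power=0.80)}")
print(f"  one-sample t, d = 0.73, power .90 -> n = "
      f"{required_n_one_sample_t(0.73, power=0.90)}")
print(f"  correlation, rho = .32, power .90 -> n = "
      f"{required_n_correlation(0.32, power=0.90)}")

wheel = cielab_wheel()  # 360 hues, L*=70, circle of radius 60 at (a*,b*)=(20,38)
print(f"\ncolor wheel: {len(wheel)} colors, L* = {wheel[0].L}")
print(f"  index   0: a* = {wheel[0].a:6.2f}, b* = {wheel[0].b:6.2f}")
print(f"  index  90: a* = {wheel[90].a:6.2f}, b* = {wheel[90].b:6.2f}")
print(wheel_frame().head(3).to_string(index=False))

# The three n's reproduce the planned cohort sizes (15/22/99); the wheel
# frame exports as CSV for display code or plotting.
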