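"""Construct the target and test translation profiles and check their kinematics.

The target translation covers a given distance in 3 s with a raised-cosine
velocity profile; the test translation is one fixed rest-to-rest motion
(half-sinusoid acceleration up to 1.55 m/s^2, then constant deceleration)
that halts at 2.5 m after 5 s.
"""

import distaniso as da
from distaniso.motion import round_half_up

for distance in (0.5, 1.5):
    prof = da.target_profile(distance)
    print(
        f"target {distance} m: peak acceleration "
        f"{round_half_up(prof.peak_acceleration, 2):.2f} m/s^2, "
        f"displacement {prof.total_distance:.3f} m in {prof.duration:.0f} s"
    )

params = da.solve_test_profile(peak_accel=1.55, total_time=5.0, total_distance=2.5)
print(
    f"test profile: acceleration phase t1 = {params.accel_phase_duration:.3f} s, "
    f"constant deceleration {round_half_up(params.decel_magnitude, 3):.3f} m/s^2"
)
profile = da.build_test_profile(params)
print(
    f"built test profile halts at {profile.total_distance:.3f} m "
    f"(final velocity {profile.velocity[-1]:.1e} m/s)"
)
# a button press 2.8 s into the test translation reproduces this distance:
print(f"position at t = 2.8 s: {da.position_at(profile, 2.8):.3f} m")
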