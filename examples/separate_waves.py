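"""Forward/backward wave separation on a waveform with a known reflection.

Builds a noise-free cycle carrying a 40% reflection arriving 60 ms after the
forward compression wave, separates it with the generating wave speed, and
shows that the backward intensity lobe appears exactly at the programmed
arrival time.
"""

import numpy as np

from awia import SyntheticSpec, differentials, generate, separate, separated_intensity

spec = SyntheticSpec(
    reflection_coefficient=0.4, reflection_delay_ms=60.0,
    noise_sd_U=0.0, noise_sd_A=0.0,
)
series, truth = generate(spec)

inc = differentials(series)
sep = separate(inc, spec.c_true)
wi = separated_intensity(sep)

cons_U = np.max(np.abs(sep.dU_plus + sep.dU_minus - inc.dU))
neg = np.flatnonzero(wi.dI_minus < -1e-14)
print(f"conservation residual  max|dU+ + dU- - dU| : {cons_U:.2e} m/s")
print(f"programmed reflection arrival              : {truth.reflection_onset_ms:.1f} ms")
print(f"backward intensity lobe onset              : {wi.t_mid[neg[0]]:.1f} ms")
print(f"peak backward intensity                    : {wi.dI_minus.min() / 1e-5:.2f} x10^-5 m/s")
print()
print("dU = dU+ + dU- holds to machine precision by construction, and the")
print("negative dI- lobe starts where the reflected (backward) wave arrives.")
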