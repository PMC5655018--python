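"""Recombination-rate profile (cM/Mb) by local cubic kernel derivatives.

Uses a telomere-biased genetic map: recombination is high near chromosome
ends and suppressed around the centromere, the canonical Triticeae
pattern. The estimator fits a weighted cubic of cM on Mb at each grid
point (Gaussian kernel, 20 Mb bandwidth) and reports the local slope.
"""

import numpy as np

from emmermap.recomb import rate_profile

x = np.linspace(0, 600, 80)                                  # Mb
u = x / 600
g = 120 * (u + 0.8 * np.sin(2 * np.pi * u) / (2 * np.pi))    # cM

prof = rate_profile(g, x, bandwidth_mb=20.0, grid_step_mb=50.0)
print("Mb     cM/Mb")
for mb, rate, ok in zip(prof.grid_mb, prof.rate, prof.valid):
    if ok:
        print(f"{mb:5.0f}  {rate:.4f}")
print("rates peak distally (~0.34 cM/Mb) and collapse at the centromere")
print("(~0.04 cM/Mb at 300 Mb), a ~9-fold suppression.")
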