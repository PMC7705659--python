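"""Date LTR retrotransposon insertions from 5'/3' LTR divergence.

Simulates elements with ages drawn from 0-4 Myr, dates them with the K80
clock at mu = 7e-9 /site/year, and prints the binned age profile — the
shape a burst of recent transposition would show.
"""

import numpy as np

from wgdclock.ltr import age_profile, date_elements
from wgdclock.simulate import simulate_ltr_elements

elements = simulate_ltr_elements(150, age_range=(0, 4e6), mu=7e-9, seed=4,
                                 ltr_length=2000)
dated = date_elements(elements, mu=7e-9, model="K80", species="focal")

true_ages = np.array([el.age_years for el in elements])
err = np.abs(dated["age_years"].to_numpy() - true_ages)
print(f"dated {len(dated)} elements; mean |error| = {err.mean()/1e6:.3f} Myr "
      "(binomial sampling noise of ~2 kb LTRs)")

profile = age_profile(dated, bin_width_myr=0.5)
print("insertion-age profile (0.5-Myr bins):")
for _, row in profile.iterrows():
    bar = "#" * int(row["count"])
    print(f"  {row.bin_lo_myr:4.1f}-{row.bin_hi_myr:4.1f} Myr  {bar} {row['count']}")
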