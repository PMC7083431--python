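"""Should subgroups get separate reference intervals? Harris-Boyd says.

The z statistic between subgroup means is compared with the sample-size
scaled critical value z* = 3*sqrt(((n1+n2)/2)/120): in huge routine
cohorts a trivially 'significant' difference is not enough — it must be
large relative to what a 120-per-group reference study resolves.
"""

import numpy as np

from refint import decide_partition, harris_boyd_critical, spearman_rho

rng = np.random.default_rng(5)
males = rng.lognormal(np.log(190.0), 0.55, size=3000)
females_young = rng.lognormal(np.log(45.0), 0.80, size=1500)
females_old = rng.lognormal(np.log(90.0), 0.70, size=1500)
females = np.concatenate([females_young, females_old])

sex = decide_partition(males, females)
print(f"male vs female:  Z={sex.z:.2f}  Z*={sex.z_star:.2f}  "
      f"separate RIs: {sex.separate}")
age = decide_partition(females_young, females_old)
print(f"female <50 vs >=50:  Z={age.z:.2f}  Z*={age.z_star:.2f}  "
      f"separate RIs: {age.separate}")

ages = np.concatenate([rng.integers(18, 50, 1500), rng.integers(50, 91, 1500)])
rho = spearman_rho(ages.astype(float), females)
print(f"female age trend: Spearman rho={rho.rho:.3f} (p={rho.p:.2g}, n={rho.n})")
print(f"(for reference, z* at the published cohort sizes 8913/5397 is "
      f"{harris_boyd_critical(8913, 5397):.2f})")
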