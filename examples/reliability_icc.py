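"""Inter-rater reliability of a CSA series as ICC(A,k).

Simulates 90 subjects measured by two raters with independent measurement
noise and reports the absolute-agreement ICC for the mean of the two
ratings, with its 95% CI, F test and interpretation band.
"""

import numpy as np

from paramuscle import generate_rater_pair, icc_a_k

rng = np.random.default_rng(0)
true_csa = rng.normal(3000.0, 400.0, 90)          # subject-level true areas, mm²
ratings = generate_rater_pair(true_csa, rater_noise_sd=120.0, seed=1)

res = icc_a_k(ratings)
print(f"ICC(A,k=2) = {res.icc:.3f}  95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]")
print(f"F({res.f_df[0]}, {res.f_df[1]}) = {res.f_value:.1f}, p = {res.f_p:.2e}")
print(f"band: {res.band}")
# With rater noise ~4% of the between-subject SD the agreement lands in
# the 'excellent' band (> 0.90); shrinking the subject spread or growing
# the rater noise degrades it toward 'poor'.
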