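"""Compare state dynamics between groups with permutation tests.

Builds a cohort in which the mindfulness group dwells longer in (and
transitions more often into) one designated state, runs the full
fit -> decode -> summarize -> test path, and prints the Table-of-results
style output: per state and property, the observed mindfulness-minus-
control difference (or dwell-KL), its permutation p-value, and the BH-FDR
decision. The designated state should be significant on all three
properties with a large positive difference; because occupancy sums to
100%, the other states absorb smaller opposite-sign shifts (sometimes
individually significant), but only the designated state shows the full
three-property signature — its dwell distribution is the only one that
actually changed.
"""

import numpy as np

from brainstates import (
    CohortDesign, EMConfig, em_fit, generate_cohort, group_difference_tests,
    match_states, summarize_cohort, viterbi_decode,
)

design = CohortDesign(n_group1=10, n_group2=10, scans_per_participant=2,
                      T=200, R=6, K=6, separation=6.0, max_dwell=30,
                      group1_designated_dwell_mean=8.0,
                      group1_p_to_designated=0.45)
manifest, scans, truth = generate_cohort(design, seed=42)

fit = em_fit(scans, design.K, EMConfig(max_iter=40, n_starts=1, max_dwell=30, seed=0))
decoded = {(s.participant_id, s.scan_id): viterbi_decode(fit.params, s) for s in scans}
summary = summarize_cohort(decoded, manifest, design.K)
tests = group_difference_tests(summary, K=design.K, n_perm=500, alpha=0.05, seed=1,
                               max_dwell=30)

perm = match_states(fit.params.means, truth.params_by_group["control"].means)
k_des = int(np.flatnonzero(perm == design.designated_state)[0])
print(f"designated contrast state maps to fitted state {k_des}\n")
print(tests.round(4).to_string(index=False))
print("\nEach permutation p uses 500 participant-level label shuffles "
      "(both scans of a participant move together); q is the BH-FDR value "
      "within each property family.")
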