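"""Test-retest reliability of a simulated cohort: ICC and Bland-Altman.

Simulates 27 control subjects measured twice under protocol 1, scores every
session, and computes both ICC forms and the Bland-Altman agreement.
"""

import numpy as np

from vrsft import (
    DeficitSampler, NoiseParams, RatingsMatrix, bland_altman, build_protocol,
    icc_agreement, icc_consistency, interpret_icc, schedule_events,
    simulate_cohort,
)
from vrsft.study import score_trace

schedule = schedule_events(build_protocol(1, "vive"))
cohort = simulate_cohort(
    n_subjects=27,
    deficit_sampler=DeficitSampler(sd=0.15, truncate=0.45),
    schedule=schedule,
    noise=NoiseParams(),
    n_sessions=2,
    master_seed=2024,
    session_deficit_sd=0.05,  # day-to-day afferent variability, log units
)

scores = {}
for sess in cohort:
    result, _ = score_trace(sess.trace, schedule)
    scores.setdefault(sess.subject_id, {})[sess.session_id] = result.score

matrix = RatingsMatrix(
    np.array([[scores[s][1], scores[s][2]] for s in sorted(scores)]),
    sorted(scores), ["test", "retest"],
)

for res in (icc_consistency(matrix), icc_agreement(matrix)):
    print(f"ICC {res.icc_type}: {res.value:.3f} "
          f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f}, p = {res.p_value:.2g}) "
          f"-> {interpret_icc(res.value, 'koo_li')} (Koo-Li), "
          f"{interpret_icc(res.value, 'cicchetti')} (Cicchetti)")

ba = bland_altman(matrix.values[:, 0], matrix.values[:, 1])
print(f"Bland-Altman: bias {ba.bias:+.4f} log units "
      f"(95% CI {ba.bias_ci_low:+.4f} to {ba.bias_ci_high:+.4f}), "
      f"LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}]")
# Bias near 0 means no systematic test-retest drift; the limits of agreement
# (bias +- 1.96 SD of differences) bound the expected disagreement between
# two measurements of the same subject.
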