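"""Shared cohort construction for the analysis drivers (regenerated by seed)."""

import sexnet as sx
from sexnet.synthetic import generate_cognitive_scores

EFFECTS = [
    sx.EffectSpec(1, "intensity_shift", "sex", 3.0),
    sx.EffectSpec(4, "intensity_shift", "pds", 3.0),
]


def load_study_cohort(seed: int = 7, n: int = 400) -> sx.SyntheticCohort:
    cohort = sx.generate_cohort(n=n, grid=16, effects=EFFECTS, seed=seed)
    cohort.records = generate_cognitive_scores(
        cohort.records, mediation_link={"list_sorting": 10.0}, seed=seed + 1
    )
    return cohort
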