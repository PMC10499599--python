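"""Shared study configuration for the analysis drivers.

Every driver regenerates the same synthetic cohort deterministically from
COHORT_SEED, so the scripts can be run independently and in any order;
outputs land under results/analysis/.
"""

from pathlib import Path

from gutmet.simulate import SimConfig, generate_cohort

COHORT_SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def load_cohort():
    RESULTS.mkdir(parents=True, exist_ok=True)
    return generate_cohort(SimConfig(seed=COHORT_SEED))
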