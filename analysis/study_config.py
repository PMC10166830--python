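"""Shared conditions for the analysis scripts.

One simulated study: a 419-subject cohort painting all 12 emotional
states, with the three trait effects (intensity, mixed pixels,
incongruency) at their default strengths.  Every numbered script
regenerates the same cohort from this seed, so each stage can be run (and
re-run) independently and reproducibly.
"""

from pathlib import Path

from embody.masks import make_body_mask
from embody.synth import SynthConfig, generate_collection

SEED = 7
N_SUBJECTS = 419
MASK_SCALE = 0.15  # coarse silhouette: every statistic reported is scale-free

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def study_collection():
    cfg = SynthConfig(n_subjects=N_SUBJECTS, seed=SEED)
    return generate_collection(cfg, mask=make_body_mask(MASK_SCALE))
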