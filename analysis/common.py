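"""Shared study configuration for the analysis drivers.

One synthetic cohort emulating the study design: a template subset whose
dual-regression maps define the empirical population prior, and a disjoint
analysis cohort scanned across 37-45 weeks postmenstrual age with a
positive age effect on within-network amplitude.
"""

from pathlib import Path

import numpy as np

from templateica import synthetic

SEED = 20260930
N_VERTICES = 400
N_SUBJECTS = 115          # 35 template + 80 analysis
N_TEMPLATE = 35
N_ICS = 4
N_TIMEPOINTS = 300
NOISE_SD = 3.0
AGE_EFFECT = 0.08         # amplitude change per week PMA

RESULTS = Path(__file__).resolve().parent.parent / "results"
TEMPLATE_FILE = RESULTS / "template.npz"

TEMPLATE_IDX = np.arange(N_TEMPLATE)
ANALYSIS_IDX = np.arange(N_TEMPLATE, N_SUBJECTS)


def load_truth():
    mesh = synthetic.make_mesh(N_VERTICES, "sphere", seed=SEED)
    return synthetic.sample_truth(
        mesh, N_SUBJECTS, N_ICS, N_TIMEPOINTS,
        noise_sd=NOISE_SD, age_effect=AGE_EFFECT, seed=SEED,
    )
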