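"""Estimate the empirical population prior from the template subjects."""

import numpy as np

import common
from templateica import io, pipeline

truth = common.load_truth()
common.RESULTS.mkdir(exist_ok=True)

template = pipeline.build_template(truth, common.TEMPLATE_IDX)
io.save_template(common.TEMPLATE_FILE, template)

r = np.corrcoef(template.mu0.ravel(), truth.group_maps.ravel())[0, 1]
r_sd = np.corrcoef(np.sqrt(template.sigma0_sq.ravel()),
                   np.sqrt(truth.between_var.ravel()))[0, 1]
clamped = np.mean(template.sigma0_sq == 0)

print(f"template from {template.n_subjects_used} subjects "
      f"(two pseudo-sessions each)")
print(f"prior mean vs true group maps: r = {r:.4f}")
# in this cohort the age effect adds real amplitude dispersion on top of
# the generative map variance, so we report the spatial pattern agreement;
# absolute-scale recovery under null-age conditions is checked in
# scripts/acceptance.py
print(f"between-subject SD vs generative SD pattern: r = {r_sd:.4f}")
print(f"variance clamped to 0 at {100 * clamped:.1f}% of (IC, vertex) pairs")
print(f"wrote {common.TEMPLATE_FILE}")
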