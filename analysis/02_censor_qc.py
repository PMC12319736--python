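"""Motion censoring report and cohort tSNR map for the analysis subjects."""

import numpy as np
import pandas as pd

import common
from templateica import censor_qc, pipeline, synthetic
from templateica.types import BoldRun

truth = common.load_truth()
common.RESULTS.mkdir(exist_ok=True)

block_length = int(pipeline.DEFAULT_BLOCK_FRACTION * truth.n_timepoints)
rows, block_runs = [], []
for i in common.ANALYSIS_IDX:
    frames = synthetic.sample_corrupt_frames(truth, int(i))
    run = synthetic.render_bold(truth, int(i), frames)
    res = censor_qc.censor_run(run, block_length=block_length)
    rows.append({
        "subject_id": run.subject_id,
        "n_corrupted_true": len(frames),
        "n_flagged": int(res.outlier_flags.sum()),
        "block_start": res.block_start,
        "outliers_in_block": res.outliers_in_block,
        "included": res.included,
    })
    if res.included:
        sl = slice(res.block_start, res.block_start + block_length)
        block_runs.append(BoldRun(run.data[sl], run.tr_seconds, run.subject_id))

report = pd.DataFrame(rows)
report.to_csv(common.RESULTS / "censoring_report.tsv", sep="\t", index=False)

tsnr = censor_qc.compute_tsnr(block_runs)
np.savetxt(common.RESULTS / "tsnr_global_db.tsv", tsnr.global_db[None],
           delimiter="\t", fmt="%.4f")

n_in = int(report["included"].sum())
print(f"censoring: block length {block_length} frames; "
      f"{n_in}/{len(report)} subjects retained")
print(f"median in-block outliers: {report['outliers_in_block'].median():.0f}")
# synthetic runs emulate demeaned, denoised BOLD, so the absolute dB level
# is far below real-scanner values; the map is meaningful relatively only
print(f"tSNR: median {np.nanmedian(tsnr.global_db):.2f} dB, "
      f"range {np.nanmin(tsnr.global_db):.2f}-{np.nanmax(tsnr.global_db):.2f} dB "
      f"(zero-mean synthetic BOLD: relative scale)")
print(f"wrote {common.RESULTS / 'censoring_report.tsv'}")
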