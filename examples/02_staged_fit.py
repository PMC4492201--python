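"""Fit the combined chemoradiation survival model to the packaged trial tables.

Runs the three-stage protocol: (1) gamma50 and D50 from X-ray-alone cohorts,
(2) chemotherapy survival CS from X-ray chemoradiation cohorts with stage-1
parameters frozen, (3) a particle-specific D50 in Gy(RBE) from proton/carbon
chemoradiation arms with gamma50 and CS frozen. Prints the parameter summary
and the chemo-equivalent dose implied by the fitted CS.
"""

import pandas as pd

from chemorad import chemo_equivalent_bed, run_full_protocol

pd.set_option("display.width", 160)

result = run_full_protocol()
cols = ["dataset", "gamma50", "gamma50_se", "d50", "d50_se", "cs", "cs_se", "n_cohorts"]
print(result.summary[cols].round(3).to_string(index=False))

stage1 = result.stages["rt_alone"]
stage2 = result.stages["chemo_all"]
equiv = chemo_equivalent_bed(stage2.free_params["cs"].value, stage1.params)
print(
    f"\nChemotherapy alone is worth a radiotherapy BED of {equiv:.0f} Gy on the "
    "fitted X-ray-alone curve -- far beyond deliverable X-ray doses, which is "
    "why chemoradiation, not radiotherapy alone, is the X-ray standard."
)
print(
    f"The particle D50 of {result.stages['cpt'].free_params['d50'].value:.0f} "
    f"Gy(RBE) vs {stage1.free_params['d50'].value:.0f} Gy for X-rays quantifies "
    "the survival advantage of charged particles at equal nominal BED."
)
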