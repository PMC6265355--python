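"""Test-retest reliability metrics on a simulated two-session cohort.

Simulates 6 subjects scanned twice, computes V_T per subject/session/
region via the GM-anchored 2TCM, and summarises ICC, AbsVar%, SEM and
MD% per region — the row structure of a test-retest reliability table.
"""

import warnings

import pandas as pd

import pkquant as pq

warnings.filterwarnings("ignore")

sim = pq.gen_trt_study(pq.PopulationModel(), n_subjects=6, seed=42)
records = []
for (subject, session), tacs in sorted(sim.tacs.items()):
    fits = pq.fit_study_2tcm(tacs, sim.blood[(subject, session)],
                             mode="gm_anchored", n_starts=20, n_refine=2)
    for region, fr in fits.items():
        records.append({
            "subject_id": subject, "session": session, "region": region,
            "outcome": "V_T", "value": pq.derive_macro(fr.params).V_T,
            "injected_dose_MBq": 300.0, "body_weight_kg": 75.0})

study = pq.StudyTable(pd.DataFrame(records))
metrics = pq.summarize_trt(study)
print(metrics.table.round(3).to_string(index=False))
print("median ICC over regions: %.2f"
      % pq.median_summary(metrics, "icc", "V_T"))
# ICC around 0.5 reflects the generator's default variance components
# (between-subject log-SD 0.20 vs session log-SD 0.13 on K1 and k3);
# MD% says how large a change must be to exceed measurement noise.
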