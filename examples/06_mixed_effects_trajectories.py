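"""Linear mixed-effects model of eGFR trajectories by follow-up DSR status.

eGFR series from generated cohorts are modelled with fixed effects for
time (years), DSR status at the follow-up ELISPOT, and their interaction,
plus a random intercept per patient.  The interaction coefficient is the
extra yearly eGFR slope of patients with donor-specific reactivity at the
follow-up sample; its p-value comes from an ML likelihood-ratio test.
"""

import pandas as pd

import camrspot as cs
from camrspot.records import AntigenClass, TimePoint

rows = []
for i in range(5):  # pool a few cohorts for a stable fit
    cohort, _ = cs.generate_cohort(cs.scenario_paper(), seed=100 + i)
    calls = cs.classify_cohort(cohort)
    for series in cohort.egfr:
        call = calls.get((series.patient_id, TimePoint.T2, AntigenClass.DONOR))
        if call is None or not call.interpretable:
            continue
        for obs in series.observations:
            rows.append({
                "patient_id": f"c{i}_{series.patient_id}",
                "time_years": obs.month / 12.0,
                "egfr": obs.egfr,
                "dsr_t2": int(call.dsr),
            })

fit = cs.fit_lmm_egfr(pd.DataFrame(rows))
print(f"reference (NDSR at follow-up) slope: {fit.time_slope:+.2f} ml/min/yr")
print(f"interaction (extra slope if DSR):    {fit.interaction_slope:+.2f} ml/min/yr")
print(f"likelihood-ratio interaction P:      {fit.interaction_p:.3g}")
print(f"random-intercept SD: {fit.random_intercept_var ** 0.5:.1f}, "
      f"residual SD: {fit.residual_var ** 0.5:.1f} ml/min")
print("\nPatients who are DSR at the follow-up sample decline several ml/min/yr")
print("faster; NDSR patients are near-flat — the generator couples the yearly")
print("slope to the follow-up functional category (-5 unregulated B-dependent,")
print("-2 regulated B-dependent, 0 otherwise).")
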