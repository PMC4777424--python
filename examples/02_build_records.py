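"""Apply the study inclusion filters and build Hb-anchored feature records.

One record per hemoglobin measurement: 90-day lookback aggregates (doses,
last labs, session means), the next-90-day planned doses, and the 3-month
hemoglobin change as the regression target.
"""

from hbforecast import (SimulationConfig, apply_inclusion_criteria,
                        build_records, simulate_cohort)

cohort = simulate_cohort(SimulationConfig(n_patients=40, calendar_days=730, seed=11))
kept, report = apply_inclusion_criteria(cohort.profiles, cohort.doses)

print(f"inclusion: {report.n_initial} patients -> "
      f"{report.n_after_followup_filter} after follow-up/prevalence -> "
      f"{report.n_after_esa_filter} after darbepoetin requirement -> "
      f"{report.n_after_dose_filter} kept")
for e in report.excluded[:5]:
    print(f"  excluded {e['patient_id']}: {e['reason']}")

records = build_records(cohort, kept)
n_valid = int(records["valid"].sum())
print(f"\n{len(records)} records, {n_valid} with a matched Hb 3 months later")

row = records[records["valid"]].iloc[10]
print(f"\nexample record at {row['anchor_date'].date()}: Hb {row['hb_t']:.1f} g/dL, "
      f"{row['esa_dose_90d']:.0f} ug darbepoetin in the past 90 d, "
      f"{row['esa_future']:.0f} ug planned in the next 90 d")
print(f"target delta-Hb = {row['delta_hb']:+.2f} g/dL "
      "(what the network learns to predict)")
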