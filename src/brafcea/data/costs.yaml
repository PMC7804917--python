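# Model costs, 2019 USD.  Per-dose intravenous drug prices are at the
# vial-rounded dose for a 1.7 m^2 / 70 kg patient (rounded up to the nearest
# single-use vial).  Oral agents are flat monthly prices with no
# administration cost.  {base, low, high} entries carry a deterministic
# sensitivity range.

drugs:
  encorafenib: {base: 8049.80, unit: per_month}          # 300 mg once daily
  regorafenib: {base: 19536.48, unit: per_month}         # 160 mg once daily
  cetuximab: {base: 3102.40, unit: per_dose}             # 500 mg
  irinotecan: {base: 39.58, unit: per_dose}              # 320 mg
  fluorouracil: {base: 15.50, unit: per_dose}            # 5000 mg
  folinic_acid: {base: 21.13, unit: per_dose}            # 350 mg
  nivolumab: {base: 6673.20, unit: per_dose}             # 240 mg
  ipilimumab: {base: 15312.80, unit: per_dose}           # 100 mg

administration:
  infusion_first_hour: {base: 143.08, low: 124.35, high: 188.20}
  infusion_additional_hour: {base: 30.99, low: 27.49, high: 39.41}
  infusion_additional_sequence: {base: 69.20, low: 60.46, high: 90.25}
  preinfusion_medication: {base: 12.30}

# Monthly monitoring while on any treatment line: office visit plus standard
# laboratory panel; CT of the abdomen/pelvis every other month (cost / 2 per
# monthly cycle).
monitoring:
  office_visit: {base: 112.80, low: 105.32, high: 152.91}
  cbc: {base: 8.63}
  cea: {base: 21.07}
  alt: {base: 5.75}
  ast: {base: 5.75}
  lipase: {base: 7.65}
  ct_abdomen_pelvis: {base: 323.99, low: 288.42, high: 417.08, every_months: 2}

end_of_life: {base: 42740.36, low: 21370.18, high: 64110.54}

# Dosing frequencies (doses per 1-month cycle), following each agent's trial
# regimen: cetuximab weekly; FOLFIRI / irinotecan every 2 weeks; nivolumab
# every 3 weeks while combined with ipilimumab (4 combination doses), then
# every 2 weeks.
dosing:
  cetuximab_doses_per_month: 4.33
  chemo_doses_per_month: 2.17
  nivo_combo_doses_per_month: 1.44
  nivo_mono_doses_per_month: 2.17
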