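# Calibration defaults for the synthetic transfer-data generator.
#
# The defaults emulate a national, regionalized interhospital ED transfer
# system over a 3-year window: ~14 referral regions of 11-17 hospitals, one
# designated base (hub) ED per region, heavy-tailed hub-concentrated
# in-degrees growing linearly with served population, mostly one-way ties,
# and arc weights spanning fewer than 36 to more than 365 transfers per
# 3 years. Record-level attribute frequencies follow the descriptive profile
# of a national transfer cohort.
n_regions: 14
hospitals_per_region: [11, 17]
n_base_per_region: 1
population_range: [100000, 4500000]  # persons served
target_slope: 5.5                    # in-degree partners per million residents
in_degree_noise_sd: 1.5
hub_attachment_strength: 8.0         # extra sender weight toward same-region hubs
region_affinity: 3.0                 # extra sender weight within the same region
reciprocity_target: 0.21             # dyadic: mutual / (mutual + asymmetric)
weight_distribution:
  law: lognormal
  mu: 3.0                            # log-scale median ~ e^3 = 20 transfers/3y
  sigma: 1.5
reciprocal_weight_mean: 2.0          # weak reverse-arc weight: 1 + Poisson(mean)
years: [2014, 2015, 2016]
yearly_growth: 1.08                  # multiplicative volume growth per year
age_mean: 55.7
age_sd: 23.8
age_max: 111
base_discharge_rate: 0.054           # P(discharged_outpatient) for ordinary senders
distributor_discharge_boost: 0.008   # additive boost for planted distributor senders
distributor_quantile: 0.05
record_attribute_tables:
  sex: {female: 0.394, male: 0.606}
  time_band: {"7a-3p": 0.399, "3p-11p": 0.415, "11p-7a": 0.186}
  reason:
    patient_request: 0.42014
    specialist_unavailable: 0.32464
    capability_problem: 0.22763
    other: 0.00527
    missing: 0.02232
  condition:
    "acute cerebrovascular disease": 0.085
    "pneumonia": 0.048
    "intracranial injury": 0.042
    "fracture of upper limb": 0.039
    "fracture of lower limb": 0.038
    "acute myocardial infarction": 0.035
    "other": 0.713
  surgery: {"yes": 0.094, "no": 0.906}
  disposition:
    ward_admission: 0.42177
    ed_observation: 0.29389
    icu_admission: 0.22390
    discharged_outpatient: 0.05509
    transferred_again: 0.00481
    transferred_back: 0.00054
seed: 0
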