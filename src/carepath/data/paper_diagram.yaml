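variables:
- name: mother_age
  role: exogenous
  measurement: categorical
  levels:
  - <20
  - 20-34
  - 35-49
  reference_level: <20
  predictor_encoding: as_levels
- name: education
  role: exogenous
  measurement: categorical
  levels:
  - no_education
  - primary_incomplete
  - primary_complete
  - secondary_incomplete
  - secondary_complete_or_higher
  reference_level: no_education
  predictor_encoding: as_levels
- name: wealth
  role: exogenous
  measurement: categorical
  levels:
  - lowest
  - second
  - middle
  - fourth
  - highest
  reference_level: lowest
  predictor_encoding: as_levels
- name: living_children
  role: exogenous
  measurement: categorical
  levels:
  - '1'
  - 2-3
  - 4+
  reference_level: '1'
  predictor_encoding: as_levels
- name: child_death_history
  role: exogenous
  measurement: binary
  levels:
  - 'no'
  - 'yes'
  reference_level: 'no'
  predictor_encoding: as_levels
- name: newborn_sex
  role: exogenous
  measurement: binary
  levels:
  - female
  - male
  reference_level: female
  predictor_encoding: as_levels
- name: facility_distance
  role: exogenous
  measurement: binary
  levels:
  - 5km_plus
  - under_5km
  reference_level: 5km_plus
  predictor_encoding: as_levels
- name: chw_visit
  role: exogenous
  measurement: binary
  levels:
  - 'no'
  - 'yes'
  reference_level: 'no'
  predictor_encoding: as_levels
- name: ds_counseling
  role: exogenous
  measurement: binary
  levels:
  - 'no'
  - 'yes'
  reference_level: 'no'
  predictor_encoding: as_levels
- name: anc4
  role: endogenous
  measurement: binary
  family: binomial
  levels:
  - 'no'
  - 'yes'
  reference_level: 'no'
  predictor_encoding: as_levels
- name: facility_delivery
  role: endogenous
  measurement: binary
  family: binomial
  levels:
  - 'no'
  - 'yes'
  reference_level: 'no'
  predictor_encoding: as_levels
- name: pnc
  role: endogenous
  measurement: binary
  family: binomial
  levels:
  - 'no'
  - 'yes'
  reference_level: 'no'
  predictor_encoding: as_levels
- name: maternal_careseeking
  role: endogenous
  measurement: binary
  family: binomial
  levels:
  - 'no'
  - 'yes'
  reference_level: 'no'
  predictor_encoding: as_levels
  na_as_reference: true
  domain_flag: had_complication
- name: knowledge
  role: endogenous
  measurement: count
  family: gaussian
  levels:
  - '0'
  - 1-4
  - 5+
  reference_level: '0'
  predictor_encoding: as_levels
- name: neonatal_careseeking
  role: endogenous
  measurement: binary
  family: binomial
  levels:
  - 'no'
  - 'yes'
  reference_level: 'no'
  predictor_encoding: as_levels
  domain_flag: sick_neonate
edges:
- parent: mother_age
  child: anc4
- parent: education
  child: anc4
- parent: wealth
  child: anc4
- parent: living_children
  child: anc4
- parent: child_death_history
  child: anc4
- parent: facility_distance
  child: anc4
- parent: chw_visit
  child: anc4
- parent: anc4
  child: facility_delivery
- parent: mother_age
  child: facility_delivery
- parent: education
  child: facility_delivery
- parent: wealth
  child: facility_delivery
- parent: living_children
  child: facility_delivery
- parent: child_death_history
  child: facility_delivery
- parent: facility_distance
  child: facility_delivery
- parent: chw_visit
  child: facility_delivery
- parent: facility_delivery
  child: pnc
- parent: anc4
  child: pnc
- parent: mother_age
  child: pnc
- parent: education
  child: pnc
- parent: wealth
  child: pnc
- parent: living_children
  child: pnc
- parent: child_death_history
  child: pnc
- parent: facility_distance
  child: pnc
- parent: chw_visit
  child: pnc
- parent: pnc
  child: maternal_careseeking
- parent: facility_delivery
  child: maternal_careseeking
- parent: anc4
  child: maternal_careseeking
- parent: mother_age
  child: maternal_careseeking
- parent: education
  child: maternal_careseeking
- parent: wealth
  child: maternal_careseeking
- parent: living_children
  child: maternal_careseeking
- parent: child_death_history
  child: maternal_careseeking
- parent: facility_distance
  child: maternal_careseeking
- parent: chw_visit
  child: maternal_careseeking
- parent: pnc
  child: knowledge
- parent: facility_delivery
  child: knowledge
- parent: anc4
  child: knowledge
- parent: mother_age
  child: knowledge
- parent: education
  child: knowledge
- parent: wealth
  child: knowledge
- parent: living_children
  child: knowledge
- parent: child_death_history
  child: knowledge
- parent: chw_visit
  child: knowledge
- parent: ds_counseling
  child: knowledge
- parent: knowledge
  child: neonatal_careseeking
- parent: maternal_careseeking
  child: neonatal_careseeking
- parent: pnc
  child: neonatal_careseeking
- parent: facility_delivery
  child: neonatal_careseeking
- parent: anc4
  child: neonatal_careseeking
- parent: mother_age
  child: neonatal_careseeking
- parent: education
  child: neonatal_careseeking
- parent: wealth
  child: neonatal_careseeking
- parent: living_children
  child: neonatal_careseeking
- parent: child_death_history
  child: neonatal_careseeking
- parent: newborn_sex
  child: neonatal_careseeking
- parent: facility_distance
  child: neonatal_careseeking
- parent: chw_visit
  child: neonatal_careseeking
- parent: ds_counseling
  child: neonatal_careseeking
outcome: neonatal_careseeking
subpopulations:
  anc4:
  - sick_neonate
  facility_delivery:
  - sick_neonate
  pnc:
  - sick_neonate
  maternal_careseeking:
  - sick_neonate
  - had_complication
  knowledge:
  - sick_neonate
  neonatal_careseeking:
  - sick_neonate
mediated_pathways:
  anc4:
  - facility_delivery
  - pnc
  - knowledge
  facility_delivery:
  - pnc
  - knowledge
  pnc:
  - knowledge
  mother_age:
  - facility_delivery
  - knowledge
  education:
  - anc4
  - facility_delivery
  - pnc
  - knowledge
  wealth:
  - anc4
  - facility_delivery
  - pnc
  living_children:
  - anc4
  - facility_delivery
  - pnc
  - knowledge
  child_death_history:
  - anc4
  newborn_sex: []
  facility_distance:
  - anc4
  - facility_delivery
  chw_visit:
  - anc4
  ds_counseling:
  - knowledge
  knowledge: []
  maternal_careseeking: []
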