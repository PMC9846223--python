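table,exposure,mediator,cell,estimate,ci_low,ci_high,stars,note
T3,anc4,facility_delivery,path_indirect,0.24,0.12,0.39,**,
T3,anc4,pnc,path_indirect,0.06,0.01,0.12,*,
T3,anc4,knowledge,path_indirect,0.09,0.02,0.16,*,
T3,anc4,,total_indirect,0.40,0.27,0.52,**,printed components sum to 0.39 unrounded
T3,anc4,,direct,0.23,0.13,0.34,**,
T3,anc4,,total,0.63,0.49,0.78,**,
T3,anc4,,mediation_proportion,63.5,,,,
T3,facility_delivery,pnc,path_indirect,0.60,0.12,1.08,*,
T3,facility_delivery,knowledge,path_indirect,-0.13,-0.24,-0.02,*,
T3,facility_delivery,,total_indirect,0.47,0.02,0.98,*,
T3,facility_delivery,,direct,0.26,0.13,0.39,**,
T3,facility_delivery,,total,0.74,0.30,1.17,*,
T3,facility_delivery,,mediation_proportion,63.5,,,,
T3,pnc,knowledge,path_indirect,0.34,0.07,0.60,*,
T3,pnc,,total_indirect,0.34,0.07,0.60,*,
T3,pnc,,direct,0.16,0.03,0.29,*,
T3,pnc,,total,0.50,0.21,0.78,**,
T3,pnc,,mediation_proportion,68.0,,,,
T3,mother_age,facility_delivery,path_indirect,0.12,0.04,0.19,**,
T3,mother_age,knowledge,path_indirect,0.08,0.002,0.16,*,
T3,mother_age,,total_indirect,0.20,0.09,0.31,**,
T3,mother_age,,total,0.20,0.09,0.31,**,
T3,education,anc4,path_indirect,0.14,0.05,0.23,**,
T3,education,facility_delivery,path_indirect,0.12,0.04,0.21,**,
T3,education,pnc,path_indirect,0.10,0.01,0.18,*,
T3,education,knowledge,path_indirect,0.12,0.01,0.22,*,
T3,education,,total_indirect,0.48,0.32,0.63,**,
T3,education,,total,0.48,0.32,0.63,**,
T3,wealth,anc4,path_indirect,0.16,0.08,0.24,**,
T3,wealth,facility_delivery,path_indirect,0.21,0.10,0.32,**,
T3,wealth,pnc,path_indirect,0.12,0.02,0.22,*,
T3,wealth,,total_indirect,0.49,0.37,0.61,**,
T3,wealth,,direct,0.37,0.25,0.50,**,
T3,wealth,,total,0.86,0.70,1.02,**,
T3,wealth,,mediation_proportion,57.0,,,,
T3,child_death_history,anc4,path_indirect,0.06,0.01,0.10,*,
T3,child_death_history,,total_indirect,0.06,0.01,0.10,*,
T3,child_death_history,,direct,-0.18,-0.33,-0.02,*,printed as "-018." in the source table
T3,child_death_history,,total,-0.12,-0.28,-0.04,,
T3,child_death_history,,mediation_proportion,-50.0,,,,
T3,living_children,anc4,path_indirect,-0.11,-0.17,-0.05,**,
T3,living_children,facility_delivery,path_indirect,-0.21,-0.31,-0.10,**,
T3,living_children,pnc,path_indirect,-0.05,-0.11,0.01,,
T3,living_children,knowledge,path_indirect,0.10,0.01,0.19,*,
T3,living_children,,total_indirect,-0.26,-0.40,-0.12,**,
T3,living_children,,total,-0.26,-0.40,-0.12,**,
T3,newborn_sex,,direct,0.18,0.10,0.23,**,
T3,newborn_sex,,total,0.18,0.10,0.23,**,
T3,facility_distance,anc4,path_indirect,0.05,0.02,0.09,*,
T3,facility_distance,facility_delivery,path_indirect,0.03,0.002,0.06,*,
T3,facility_distance,,total_indirect,0.08,0.04,0.13,**,
T3,facility_distance,,direct,0.12,0.03,0.21,**,
T3,facility_distance,,total,0.20,0.10,0.30,**,
T3,facility_distance,,mediation_proportion,40.0,,,,
T3,chw_visit,anc4,path_indirect,0.24,0.13,0.36,**,
T3,chw_visit,,total_indirect,0.24,0.13,0.36,**,
T3,chw_visit,,total,0.24,0.13,0.36,**,
T3,ds_counseling,knowledge,path_indirect,0.08,-0.01,0.18,,
T3,ds_counseling,,total_indirect,0.08,-0.01,0.18,,
T3,ds_counseling,,direct,0.11,0.01,0.22,*,
T3,ds_counseling,,total,0.20,0.06,0.34,*,
T3,ds_counseling,,mediation_proportion,40.0,,,,
T3,knowledge,,direct,0.37,0.09,0.64,*,
T3,knowledge,,total,0.37,0.09,0.64,*,
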