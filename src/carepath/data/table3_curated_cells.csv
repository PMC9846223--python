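exposure,mediator,cell,route,included,justification
anc4,facility_delivery,path_indirect,recompute,True,
anc4,pnc,path_indirect,recompute,True,
anc4,knowledge,path_indirect,recompute,True,
anc4,,total_indirect,recompute,False,printed 0.40 is the sum of the already-rounded components; the unrounded products sum to 0.39
anc4,,direct,recompute,True,
anc4,,total,recompute,False,inherits the total-indirect rounding cascade (unrounded pipeline gives 0.62 vs printed 0.63)
anc4,,mediation_proportion,printed_components,True,
facility_delivery,pnc,path_indirect,recompute,False,ln(41.22)*ln(1.18)=0.62 vs printed 0.60; the printed cell reflects unrounded source coefficients
facility_delivery,knowledge,path_indirect,recompute,True,
facility_delivery,,total_indirect,recompute,False,depends on the irreproducible PNC-path cell
facility_delivery,,direct,recompute,True,
facility_delivery,,total,recompute,False,depends on the irreproducible PNC-path cell
facility_delivery,,mediation_proportion,printed_components,True,
pnc,knowledge,path_indirect,recompute,False,printed 0.34 is about twice any knowledge-to-outcome coefficient consistent with the printed sources (0.46*0.36=0.17)
pnc,,total_indirect,recompute,False,equals the irreproducible knowledge-path cell
pnc,,direct,recompute,False,ln(1.18)=0.166 rounds to 0.17 vs printed 0.16; reflects unrounded source coefficients
pnc,,total,recompute,False,depends on the irreproducible components
pnc,,mediation_proportion,printed_components,True,
mother_age,facility_delivery,path_indirect,recompute,True,
mother_age,knowledge,path_indirect,recompute,True,
mother_age,,total_indirect,recompute,True,
mother_age,,total,recompute,True,
education,anc4,path_indirect,recompute,True,
education,facility_delivery,path_indirect,recompute,False,mean(ln 1.39; ln 1.88)*ln(1.30)=0.126 rounds to 0.13 vs printed 0.12; reflects unrounded source coefficients
education,pnc,path_indirect,recompute,True,
education,knowledge,path_indirect,recompute,True,
education,,total_indirect,recompute,True,
education,,total,recompute,True,
wealth,anc4,path_indirect,recompute,True,
wealth,facility_delivery,path_indirect,recompute,True,
wealth,pnc,path_indirect,recompute,False,printed 0.12 is not reproducible from the printed coefficients under either averaging mode (significant-levels gives 0.05; all-levels 0.04)
wealth,,total_indirect,recompute,False,depends on the irreproducible PNC-path cell
wealth,,direct,recompute,True,
wealth,,total,recompute,False,depends on the irreproducible PNC-path cell
wealth,,mediation_proportion,printed_components,True,
child_death_history,anc4,path_indirect,recompute,True,
child_death_history,,total_indirect,recompute,True,
child_death_history,,direct,recompute,False,ln(0.84)=-0.174 rounds to -0.17 vs printed -0.18; reflects unrounded source coefficients
child_death_history,,total,recompute,False,depends on the direct cell
child_death_history,,mediation_proportion,printed_components,True,
living_children,anc4,path_indirect,recompute,True,
living_children,facility_delivery,path_indirect,recompute,False,mean(ln 0.63; ln 0.34)*ln(1.30)=-0.202 rounds to -0.20 vs printed -0.21; reflects unrounded source coefficients
living_children,pnc,path_indirect,recompute,True,
living_children,knowledge,path_indirect,recompute,True,
living_children,,total_indirect,recompute,True,
living_children,,total,recompute,True,
newborn_sex,,direct,recompute,True,
newborn_sex,,total,recompute,True,
facility_distance,anc4,path_indirect,recompute,True,
facility_distance,facility_delivery,path_indirect,recompute,True,
facility_distance,,total_indirect,recompute,True,
facility_distance,,direct,recompute,True,
facility_distance,,total,recompute,True,
facility_distance,,mediation_proportion,printed_components,True,
chw_visit,anc4,path_indirect,recompute,False,ln(2.89)*ln(1.26)=0.245 rounds to 0.25 vs printed 0.24; reflects unrounded source coefficients
chw_visit,,total_indirect,recompute,False,equals the ANC-path cell
chw_visit,,total,recompute,False,equals the ANC-path cell
ds_counseling,knowledge,path_indirect,recompute,False,printed 0.08 is about twice 0.12*ln(1.44)=0.04 computed from the printed sources
ds_counseling,,total_indirect,recompute,False,equals the irreproducible knowledge-path cell
ds_counseling,,direct,recompute,True,
ds_counseling,,total,recompute,False,depends on the irreproducible knowledge-path cell
ds_counseling,,mediation_proportion,printed_components,True,
knowledge,,direct,recompute,False,ln(1.44)=0.365 rounds to 0.36 vs printed 0.37; reflects unrounded source coefficients
knowledge,,total,recompute,False,equals the direct cell
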