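# Synthetic stand-in for a young in-vivo lower-limb architecture dataset
# (desk-scale, 12 representative muscles across 6 functional groups).
muscle,Vm_mm3,Lf_mm,Ls_um,pennation_deg,n_actuators
soleus,450000,60,2.12,22,1
gastrocnemius,320000,65,2.59,17,1
tibialis_anterior,140000,75,3.14,11,1
ext_digitorum,60000,80,3.12,9,1
vastus_lateralis,500000,100,2.14,18,1
vastus_medialis,430000,97,2.24,16,1
rectus_femoris,270000,80,2.42,14,1
biceps_femoris,230000,95,2.35,12,1
semitendinosus,190000,170,2.89,8,1
gluteus_maximus,850000,150,2.60,20,3
iliopsoas,300000,110,2.70,12,1
adductor_magnus,550000,125,2.19,13,2
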