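# Synthetic stand-in for an elderly cadaveric lower-limb architecture dataset.
# Relative to the young table: lower volumes and maximum forces, shorter
# fibres (most strongly in distal functional groups), smaller pennation.
muscle,Vm_mm3,Lf_mm,Ls_um,pennation_deg,n_actuators
soleus,280000,44,2.12,17.6,1
gastrocnemius,200000,51,2.59,13.6,1
tibialis_anterior,87000,68,3.14,8.8,1
ext_digitorum,37000,69,3.12,7.2,1
vastus_lateralis,340000,84,2.14,14.4,1
vastus_medialis,292000,80,2.24,12.8,1
rectus_femoris,184000,66,2.42,11.2,1
biceps_femoris,156000,80,2.35,9.6,1
semitendinosus,129000,145,2.89,6.4,1
gluteus_maximus,638000,135,2.60,16,3
iliopsoas,225000,100,2.70,9.6,1
adductor_magnus,413000,113,2.19,10.4,2
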