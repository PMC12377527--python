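category,molecules,relaxation_path,md,scan
small initial (Nh<=10),8878,30092,0,0
small concurrent (Nh<=10),0,0,186450,0
medium (10<Nh<=20),81835,365359,337903,0
screened (10<Nh<=70),6500,41975,89781,0
large (20<Nh<=70),0,0,114614,0
torsion (Nh=20),0,0,160328,37085
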