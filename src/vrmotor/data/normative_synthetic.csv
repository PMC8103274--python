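region,side,age_min,age_max,mean_sbr,sd_sbr
striatum,left,30,50,2.75,0.30
striatum,left,50,65,2.60,0.30
striatum,left,65,80,2.45,0.30
striatum,left,80,95,2.35,0.30
striatum,right,30,50,2.75,0.30
striatum,right,50,65,2.60,0.30
striatum,right,65,80,2.45,0.30
striatum,right,80,95,2.35,0.30
caudate,left,30,50,2.90,0.35
caudate,left,50,65,2.75,0.35
caudate,left,65,80,2.60,0.35
caudate,left,80,95,2.50,0.35
caudate,right,30,50,2.90,0.35
caudate,right,50,65,2.75,0.35
caudate,right,65,80,2.60,0.35
caudate,right,80,95,2.50,0.35
putamen,left,30,50,2.60,0.30
putamen,left,50,65,2.45,0.30
putamen,left,65,80,2.30,0.30
putamen,left,80,95,2.20,0.30
putamen,right,30,50,2.60,0.30
putamen,right,50,65,2.45,0.30
putamen,right,65,80,2.30,0.30
putamen,right,80,95,2.20,0.30
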