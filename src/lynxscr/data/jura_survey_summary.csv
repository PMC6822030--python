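survey,region,n_cameras,mean_trap_days,n_occasions,n_detections,n_individuals,n_female,n_unknown,n_male,trap_days
2011_Doubs,Jura,48,63,15,22,4,1,1,2,
2011_Jura,Jura,66,59,15,42,9,1,7,1,
2012_Jura-Doubs,Jura,148,69,17,130,21,2,14,5,
2013_Doubs,Jura,44,63,14,25,6,1,4,1,
2013_Ain-Jura,Jura,142,58,13,117,19,2,13,4,
2014_Ain,Jura,118,59,13,158,23,4,16,3,
2015_Ain,Jura,30,99,21,38,10,2,8,0,
2011-2016_Vosges,Vosges,230,,,0,0,0,0,0,6804
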