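survey,scr_abundance,scr_abundance_se,scr_density,scr_density_se,m0_abundance,m0_abundance_se,mh_abundance,mh_abundance_se,mmdm_km,eta_mmdm_km2,m0_density_mmdm,m0_density_mmdm_se,mh_density_mmdm,mh_density_mmdm_se,eta_hmmdm_km2,m0_density_hmmdm,m0_density_hmmdm_se,mh_density_hmmdm,mh_density_hmmdm_se
2011_Doubs,5,0.1,0.24,0.02,4,0.7,5,1.7,9.1,1991,0.31,0.05,0.39,0.13,697,0.57,0.10,0.72,0.24
2011_Jura,12,0.1,0.44,0.02,9,0.7,10,1.8,16.2,2930,0.31,0.02,0.34,0.06,1491,0.60,0.05,0.67,0.12
2012_Jura-Doubs,29,0.2,0.67,0.02,21,0.6,25,2.8,8.9,3089,0.68,0.02,0.81,0.09,2111,0.99,0.03,1.18,0.13
2013_Doubs,7,0.1,0.36,0.02,6,0.3,7,1.2,9.1,1171,0.51,0.02,0.60,0.10,659,0.91,0.05,1.06,0.18
2013_Ain-Jura,21,0.1,0.54,0.02,19,0.8,25,4.1,18.2,4954,0.38,0.02,0.50,0.08,2673,0.71,0.03,0.93,0.15
2014_Ain,29,0.2,0.91,0.03,23,0.7,28,3.6,13.6,2936,0.78,0.02,0.95,0.12,1668,1.38,0.04,1.68,0.21
2015_Ain,12,0.1,0.64,0.03,11,1.2,11,1.2,12.1,1549,0.71,0.08,0.70,0.08,753,1.46,0.16,1.43,0.16
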