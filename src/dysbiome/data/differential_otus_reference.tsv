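# Differentially abundant OTUs between lesional (vitiligo) and non-lesional
# (normal) skin, as retained by the bootstrapped median/rank-sum procedure
# (BH correction at FDR 1e-4, 99.5% retention over 1000 bootstraps).
# Percent units throughout; higher_in flags the class with higher median.
otu_id	phylum	rel_contrib_non_lesional	rel_contrib_lesional	median_non_lesional	min_non_lesional	max_non_lesional	median_lesional	min_lesional	max_lesional	higher_in
OTU_105_Skermanella	Proteobacteria	0.160	0.400	0.056	0.000	1.086	0.014	0.000	7.974	non_lesional
OTU_128_Jeotgalicoccus	Firmicutes	0.050	0.020	0.007	0.000	0.340	0.000	0.000	0.312	non_lesional
OTU_130_Peptostreptococcus	Firmicutes	0.270	0.120	0.135	0.006	1.128	0.098	0.000	0.664	non_lesional
OTU_133_Turicibacter	Firmicutes	0.070	0.040	0.043	0.000	0.418	0.020	0.000	0.141	non_lesional
OTU_348_Phyllobacteriaceae	Proteobacteria	0.040	0.080	0.021	0.000	0.181	0.010	0.000	0.317	non_lesional
OTU_593_Aeromicrobium	Actinobacteria	0.020	0.020	0.007	0.000	0.128	0.000	0.000	0.094	non_lesional
OTU_946_Clostridiaceae	Firmicutes	0.020	0.010	0.012	0.000	0.063	0.000	0.000	0.066	non_lesional
OTU_1020_Kineococcus	Actinobacteria	0.010	0.020	0.007	0.000	0.035	0.000	0.000	0.106	non_lesional
OTU_1078_Massilia	Proteobacteria	0.040	0.020	0.029	0.000	0.134	0.009	0.000	0.081	non_lesional
OTU_1159_Rubellimicrobium	Proteobacteria	0.080	0.060	0.052	0.000	0.222	0.019	0.000	0.239	non_lesional
OTU_1292_Pedobacter	Bacteroidetes	0.010	0.000	0.005	0.000	0.054	0.000	0.000	0.016	non_lesional
OTU_1469_Sarcina	Firmicutes	0.020	0.020	0.014	0.000	0.188	0.005	0.000	0.185	non_lesional
OTU_1621_Anaerococcus	Firmicutes	0.010	0.010	0.008	0.000	0.087	0.000	0.000	0.080	non_lesional
OTU_1674_Schlegelella	Proteobacteria	0.010	0.010	0.014	0.000	0.054	0.000	0.000	0.040	non_lesional
OTU_1763_Sanguibacter	Actinobacteria	0.020	0.030	0.019	0.000	0.126	0.009	0.000	0.275	non_lesional
OTU_32_Propionibacterium	Actinobacteria	7.690	10.350	1.419	0.217	48.211	2.955	0.188	51.543	lesional
OTU_1239_Thermomonas	Proteobacteria	0.040	0.030	0.015	0.000	0.180	0.021	0.000	0.199	lesional
OTU_1_Enterobacteriaceae	Proteobacteria	0.830	1.200	0.126	0.000	4.800	0.278	0.000	4.277	lesional
OTU_19_Xanthomonadaceae	Proteobacteria	0.290	0.480	0.106	0.029	0.976	0.256	0.000	1.837	lesional
OTU_1577_Sphingomonas	Proteobacteria	0.190	0.430	0.079	0.006	1.068	0.122	0.010	1.789	lesional
OTU_1670_Roseomonas	Proteobacteria	0.010	0.020	0.000	0.000	0.144	0.009	0.000	0.107	lesional
OTU_57_Chryseobacterium	Bacteroidetes	0.420	0.680	0.291	0.068	1.941	0.437	0.011	1.692	lesional
OTU_85_Roseomonas	Proteobacteria	0.020	0.030	0.008	0.000	0.053	0.024	0.000	0.127	lesional
OTU_111_Streptococcus	Firmicutes	0.120	0.250	0.091	0.000	0.476	0.180	0.000	1.035	lesional
OTU_115_Bacilli	Firmicutes	0.240	0.340	0.029	0.000	1.582	0.083	0.000	1.175	lesional
OTU_423_TM7_genera_incertae_sedis	TM7	0.030	0.020	0.011	0.000	0.117	0.029	0.000	0.077	lesional
OTU_545_Cellvibrio	Proteobacteria	0.010	0.020	0.000	0.000	0.026	0.007	0.000	0.183	lesional
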