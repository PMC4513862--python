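# Column schema for the CSV artifacts written by the pipeline.  version: 1
file,column,description
landscape_<system>.csv,n_inter,number of inter-strand base pairs (bin coordinate)
landscape_<system>.csv,n_intra,total intra-strand base pairs on both strands (bin coordinate)
landscape_<system>.csv,dG_kT,free energy of the bin in kBT relative to the fully unpaired (0;0) bin
landscape_<system>.csv,se,standard error of dG_kT (replica scatter + stitch drift)
landscape_<system>.csv,n_samples,raw Monte Carlo sample count in the bin
landscape_<system>.csv,censored,1 if dG_kT >= 10 kBT above the reference (reported but unreliable)
melt_<system>.csv,T_C,temperature in degrees Celsius
melt_<system>.csv,yield,equilibrium fraction of states with >= 1 intra-strand pair
melt_<system>.csv,se,standard error of the yield (block estimate)
rate_table.csv,system,system label (reference row has ratio 1 everywhere)
rate_table.csv,k_plus_ratio,k0+/k+ hybridization slowdown relative to the reference
rate_table.csv,keq_ratio,Keq0/Keq equilibrium-constant ratio relative to the reference
rate_table.csv,k_minus_ratio,k-/k-0 melting acceleration inferred by detailed balance
rate_table.csv,r_plus_ratio,r0+/r+ first-contact (0 to 1 inter pair) rate ratio
rate_table.csv,P_plus_ratio,P0+/P+ success-probability (1 pair to full duplex) ratio
rate_table.csv,dG0_kT,standard-state duplex formation free energy in kBT
rate_table.csv,*_se,standard error of the like-named column
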