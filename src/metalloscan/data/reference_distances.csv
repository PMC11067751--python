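# Small-molecule survey reference distances for fac-[Re(CO)3]+ to protein-like
# donor atoms, mean and standard uncertainty in Angstrom (CSD survey averages).
metal,donor_context,mean,su
Re,imidazole_N,2.185,0.007
Re,carboxylate_O,2.14,0.06
Re,amide_N,2.18,0.01
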