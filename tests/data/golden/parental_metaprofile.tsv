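offset	mean_partition	n_origins
-2250	-0.86375207396703058	4
-1750	-0.53090261760064683	4
-1250	-0.27095456582723398	4
-750	-0.095280977893061419	4
-250	0.010978966530591282	4
250	0.014436629661670999	4
750	0.12755093648383592	4
1250	0.28791242367135683	4
1750	0.57967229289695688	4
2250	0.89503932244404116	4
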