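# Published accuracy metrics for the 18 long-read silky-shark mitogenome
# assemblies benchmarked against the short-read gold-standard reference.
# Columns: assembly name, contig topology, length (bp), coverage (x-fold),
# uncorrected p-distance to the reference, total error count.
name	circular	length	coverage	p_dist	errors
Flye +1p	true	16690	20	0.001023172	65
Flye +1p + Medaka	true	16475	20	0.000541679	70
Flye +5p	true	16691	20	0.001023172	69
Flye +5p + Medaka	true	16475	20	0.000541679	71
Flye +10p	true	16691	20	0.001023172	69
Flye +10p + Medaka	true	16475	20	0.000541679	71
Unicycler - N	true	16801	2.28	0.001143545	110
Unicycler - N + Medaka	true	16781	2.28	0.000601866	89
Unicycler - B	true	16801	2.28	0.001143545	110
Unicycler - B + Medaka	true	16781	2.28	0.000601866	89
Unicycler - C	true	16801	2.28	0.001143545	110
Unicycler - C + Medaka	true	16781	2.28	0.000601866	89
Rebaler - C. amblyrhynchos	true	15782	50.59	0.001324105	106
Rebaler - C. ambly. + Medaka	true	16774	50.59	0.000541679	81
Rebaler - C. amboinensis	true	15790	49.94	0.000902799	95
Rebaler - C. ambo. + Medaka	true	16776	49.94	0.000361119	73
Rebaler - C. falciformis	true	16789	52.52	0.000842612	96
Rebaler - C. falci. + Medaka	true	16777	52.52	0.000541679	81
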