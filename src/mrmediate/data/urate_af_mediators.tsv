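mediator	total_or_ci	total_p	step1_or_ci	step1_p	step2_or_ci	step2_p	direction	classification	mediating_ratio
Complement C1q tumor necrosis factor-related protein 1	1.045(1.007~1.083)	0.019	1.214(1.075~1.372)	0.002	1.022(1.004~1.040)	0.002	TRUE	Partial	0.10%
SAGA-associated factor 29 homolog	1.045(1.007~1.083)	0.019	1.357(1.035~1.779)	0.042	1.029(1.005~1.053)	0.042	TRUE	Partial	0.20%
C-C motif chemokine 27	1.045(1.007~1.083)	0.019	1.209(1.057~1.382)	0.005	1.063(1.005~1.124)	0.005	TRUE	Partial	0.26%
Carboxypeptidase B	1.045(1.007~1.083)	0.019	1.221(1.112~1.341)	<0.001	1.082(1.016~1.153)	<0.001	TRUE	Partial	0.36%
Corticoliberin	1.045(1.007~1.083)	0.019	1.165(1.057~1.284)	0.002	1.028(1.002~1.055)	0.002	TRUE	Partial	0.10%
Casein kinase II subunit alpha	1.045(1.007~1.083)	0.019	1.155(1.029~1.295)	0.014	1.039(1.018~1.059)	0.014	TRUE	Partial	0.12%
Tumor necrosis factor receptor superfamily member 27	1.045(1.007~1.083)	0.019	1.132(1.002~1.278)	0.046	1.021(1.000~1.043)	0.046	TRUE	Partial	0.06%
Granzyme K	1.045(1.007~1.083)	0.019	0.868(0.782~0.963)	0.008	0.929(0.877~0.984)	0.008	TRUE	Partial	0.24%
Hepcidin	1.045(1.007~1.083)	0.019	1.172(1.052~1.305)	0.004	1.033(1.007~1.060)	0.004	TRUE	Partial	0.12%
Hepatocyte nuclear factor 4-alpha	1.045(1.007~1.083)	0.019	1.154(1.032~1.292)	0.012	1.047(1.004~1.092)	0.012	TRUE	Partial	0.15%
Interleukin-3 receptor subunit alpha	1.045(1.007~1.083)	0.019	0.893(0.804~0.992)	0.035	0.968(0.941~0.995)	0.035	TRUE	Partial	0.09%
Probable E3 ubiquitin-protein ligase MID2	1.045(1.007~1.083)	0.019	1.109(1.001~1.228)	0.047	1.041(1.009~1.074)	0.047	TRUE	Partial	0.10%
Syntaxin-10	1.045(1.007~1.083)	0.019	1.185(1.057~1.329)	0.004	1.019(1.002~1.037)	0.004	TRUE	Partial	0.07%
Tumor necrosis factor receptor superfamily member 1B	1.045(1.007~1.083)	0.019	1.147(1.037~1.270)	0.008	1.066(1.009~1.127)	0.008	TRUE	Partial	0.20%
Tumor necrosis factor receptor superfamily member 21	1.045(1.007~1.083)	0.019	1.131(1.011~1.265)	0.031	1.029(1.005~1.054)	0.031	TRUE	Partial	0.08%
Troponin I, cardiac muscle	1.045(1.007~1.083)	0.019	1.090(1.003~1.184)	0.042	1.068(1.009~1.131)	0.042	TRUE	Partial	0.13%
Ubiquitin carboxyl-terminal hydrolase 25	1.045(1.007~1.083)	0.019	1.142(1.033~1.262)	0.010	1.015(1.001~1.030)	0.010	TRUE	Partial	0.05%
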