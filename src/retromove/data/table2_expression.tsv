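# Sex-biased expression (log male/female ratio; positive = male-biased) of
# the 21 retrogenes in six Drosophila species, from published microarray data.
# Dialect: tab-separated; '-' = missing; trailing '*' = significant after
# Mann-Whitney U + FDR correction; '**bold**' = species carries the
# retroposed copy (annotation only).
gene	Dsim	Dyak	Dana	Dpse	Dvir	Dmoj
CG11164	-0.396*	-0.214	-0.366	-0.369	**-0.431**	**-0.449**
CG11790	0.652	-0.198	-0.139	-1.116*	**-0.209**	**-0.822***
CG12375	**0.062**	**-0.065**	**-0.248**	-0.486	-0.181	0.077
CG1354	-0.471*	-0.597*	**-0.358***	-0.629*	-0.988*	-0.636*
CG14286	**0.378**	**-0.505**	-	0.076	-0.457	-0.961*
CG14618	-0.184	-0.112	-0.064	0.000	**-0.149**	**-0.431***
CG14779	-0.036	-0.176	**0.116**	-0.244	-0.151	-0.915
CG1639	-0.052	-0.323	0.019	**-0.402**	0.358*	-0.177
CG16771	**0.414**	**0.163**	**-0.043**	-	-0.082	0.037
CG2059	0.251	0.130	**0.039**	0.181	0.154	0.137
CG2227	**-0.151***	**0.128**	**-0.130**	**-0.085**	-0.212	-
CG32441	0.713	0.432	0.002	-0.368*	**0.587***	**-0.082**
CG33250	-0.068	-0.321	**-0.071**	-0.286	-	-
CG4918	**-0.807***	**-0.772***	-1.911*	-2.491*	-1.284*	-
CG5029	0.937*	0.349*	-0.550*	-0.361*	**0.140**	**0.615***
CG6284	**-0.216**	**-0.223**	**0.040**	-	-0.214	-0.622*
CG8239	-	-0.298	-	-	**0.044**	**-0.323**
CG8939	-0.512*	-0.449*	**-0.398**	-1.489*	-0.401	-0.271
CG9126	-	-0.003	**-0.017**	-	-	-
CG9172	**0.112**	**0.331***	**-0.842***	**-0.610***	-0.164	0.245
CG9742	-0.577	-0.727*	-0.356	**-0.618***	-0.258	-0.915*
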