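# SYNTHETIC GO-slim annotation table for the 35-protein fixture.
# This is a reconstruction assembled for testing the profiling mechanics,
# consistent with the study narrative (e.g. 10 of the 11 common proteins
# extracellular, regulation-dominated biological processes); it is NOT
# authoritative Gene Ontology data.
accession	aspect	term
4505821	cellular_component	extracellular region
4505821	biological_process	biological regulation
4505821	biological_process	defense response
4506885	cellular_component	extracellular region
4506885	biological_process	biological regulation
4506885	biological_process	cell morphogenesis
4502027	cellular_component	extracellular region
4502027	biological_process	transport
4502027	biological_process	biological regulation
54607120	cellular_component	extracellular region
54607120	cellular_component	secretory granule
54607120	biological_process	defense response
54607120	biological_process	transport
54607120	biological_process	biological regulation
5453678	cellular_component	extracellular region
5453678	cellular_component	lysosome
5453678	biological_process	transport
5453678	biological_process	biological regulation
221316614	cellular_component	extracellular region
221316614	biological_process	biological regulation
221316614	biological_process	signal transduction
11386147	cellular_component	extracellular region
11386147	cellular_component	lysosome
11386147	biological_process	transport
11386147	biological_process	biological regulation
4503143	cellular_component	lysosome
4503143	cellular_component	intracellular organelle
4503143	biological_process	protein metabolic process
4503143	biological_process	biological regulation
4502173	cellular_component	extracellular region
4502173	biological_process	protein metabolic process
4502173	biological_process	biological regulation
4502337	cellular_component	extracellular region
4502337	cellular_component	plasma membrane
4502337	biological_process	signal transduction
4502337	biological_process	immune system process
4502337	biological_process	biological regulation
42716297	cellular_component	extracellular region
42716297	cellular_component	secretory granule
42716297	biological_process	signal transduction
42716297	biological_process	biological regulation
151301154	cellular_component	extracellular region
151301154	biological_process	biological regulation
4503109	cellular_component	extracellular region
4503109	biological_process	biological regulation
4503109	biological_process	protein metabolic process
5031863	cellular_component	extracellular region
5031863	biological_process	immune system process
5031863	biological_process	signal transduction
38049014	cellular_component	extracellular region
38049014	biological_process	biological regulation
38049014	biological_process	cell morphogenesis
6382064	cellular_component	extracellular region
6382064	cellular_component	lysosome
6382064	biological_process	protein metabolic process
6382064	biological_process	biological regulation
4503107	cellular_component	extracellular region
4503107	biological_process	biological regulation
4503107	biological_process	protein metabolic process
4507509	cellular_component	extracellular region
4507509	biological_process	biological regulation
4507509	biological_process	signal transduction
4757826	cellular_component	extracellular region
4757826	cellular_component	plasma membrane
4757826	biological_process	immune system process
4757826	biological_process	defense response
31543380	cellular_component	cytosol
31543380	cellular_component	nucleus
31543380	biological_process	stress response
31543380	biological_process	biological regulation
56676397	cellular_component	nucleus
56676397	biological_process	biological regulation
167857790	cellular_component	extracellular region
167857790	biological_process	defense response
167857790	biological_process	transport
50363217	cellular_component	extracellular region
50363217	biological_process	biological regulation
50363217	biological_process	protein metabolic process
4557871	cellular_component	extracellular region
4557871	cellular_component	endosome
4557871	biological_process	transport
4557871	biological_process	biological regulation
4507065	cellular_component	extracellular region
4507065	biological_process	defense response
4507065	biological_process	protein metabolic process
4506713	cellular_component	cytosol
4506713	cellular_component	nucleus
4506713	cellular_component	ribosome
4506713	biological_process	protein metabolic process
104487006	cellular_component	plasma membrane
104487006	biological_process	signal transduction
104487006	biological_process	biological regulation
104487006	biological_process	stress response
25121982	cellular_component	extracellular region
25121982	biological_process	biological regulation
25121982	biological_process	cell morphogenesis
32171249	cellular_component	extracellular region
32171249	cellular_component	nucleus
32171249	biological_process	transport
32171249	biological_process	vesicle-mediated transport
32171249	biological_process	defense response
4503139	cellular_component	lysosome
4503139	cellular_component	vesicle
4503139	biological_process	protein metabolic process
4503139	biological_process	vesicle-mediated transport
19923082	cellular_component	extracellular region
19923082	biological_process	defense response
4505529	cellular_component	extracellular region
4505529	biological_process	defense response
4505529	biological_process	transport
110735433	cellular_component	plasma membrane
110735433	biological_process	immune system process
4503009	cellular_component	secretory granule
4503009	cellular_component	vesicle
4503009	biological_process	protein metabolic process
4503009	biological_process	vesicle-mediated transport
47132551	cellular_component	extracellular region
47132551	biological_process	cell morphogenesis
47132551	biological_process	biological regulation
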