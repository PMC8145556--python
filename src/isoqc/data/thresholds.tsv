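taxon	rank	metric	low	high	criticality
all	global	q30_fraction	0.90		critical
all	global	species_purity	0.95		critical
all	global	mlst_duplicated		0	warn
all	global	duplicated_core_count		1	warn
all	global	snv_contaminated		0	critical
Salmonella enterica	species	coverage_depth	30		critical
Salmonella enterica	species	assembly_length	4500000	5100000	critical
Salmonella enterica	species	n_contigs	42	216	warn
Salmonella enterica	species	gc_percent	48.1	56.1	warn
Salmonella enterica	species	unique_core_fraction	95		warn
Salmonella enterica	species	n50	53000		warn
Salmonella enterica	species	duplication_ratio		1.002	warn
Listeria monocytogenes	species	coverage_depth	20		critical
Listeria monocytogenes	species	assembly_length	2800000	3200000	critical
Listeria monocytogenes	species	n_contigs	18	212	warn
Listeria monocytogenes	species	gc_percent	33.9	41.9	warn
Listeria monocytogenes	species	unique_core_fraction	95		warn
Listeria monocytogenes	species	n50	60000		warn
Listeria monocytogenes	species	duplication_ratio		1.005	warn
Escherichia coli	species	coverage_depth	40		critical
Escherichia coli	species	assembly_length	4500000	5600000	critical
Escherichia coli	species	n_contigs	116	618	warn
Escherichia coli	species	gc_percent	42.6	54.6	warn
Escherichia coli	species	unique_core_fraction	95		warn
Escherichia coli	species	n50	71700		warn
Escherichia coli	species	duplication_ratio		1.015	warn
Campylobacter	genus	coverage_depth	20		critical
Campylobacter	genus	assembly_length	1400000	2000000	critical
Campylobacter	genus	n_contigs	15	112	warn
Campylobacter	genus	gc_percent	26.4	35.3	warn
Campylobacter	genus	unique_core_fraction	79		warn
Campylobacter	genus	n50	54200		warn
Campylobacter	genus	duplication_ratio		1.009	warn
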