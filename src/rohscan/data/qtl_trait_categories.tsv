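# QTL trait -> category mapping (case-insensitive on the trait column).
# Categories: reproduction, growth, meat_and_carcass, health.
# Seeded with AnimalQTLdb top-level trait classes and common pig trait names;
# extend or override with --categories.
Reproduction	reproduction
Litter size	reproduction
Number born alive	reproduction
Number of stillborn	reproduction
Ovary weight	reproduction
Teat number	reproduction
Testicular weight	reproduction
Testosterone level	reproduction
Age at puberty	reproduction
Gestation length	reproduction
Production	growth
Growth	growth
Average daily gain	growth
Body weight	growth
Body length	growth
Thoracic vertebra number	growth
Feed conversion ratio	growth
Average backfat thickness	growth
Meat and Carcass Quality	meat_and_carcass
Meat and Carcass	meat_and_carcass
Drip loss	meat_and_carcass
Intramuscular fat content	meat_and_carcass
Muscle pH	meat_and_carcass
pH 24 hr post-mortem	meat_and_carcass
Meat color score	meat_and_carcass
Marbling	meat_and_carcass
Loin muscle area	meat_and_carcass
Carcass weight	meat_and_carcass
Fat content	meat_and_carcass
Health	health
Immune capacity	health
Interferon-gamma level	health
White blood cell number	health
Hematocrit	health
Disease resistance	health
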