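mode	correlation	coexpression	phenotype	pathway_enrichment	go_enrichment
T-P-M	Yes	Yes	Yes	Yes	Yes
T-P	Yes, M is derived from the literature.	Yes	Yes	No	Yes
P-M	Yes, T is derived from the literature.	Yes	Yes	Yes	No
T-M	Yes, P is derived from the literature.	Yes	Yes	Yes	Yes
T	Yes	Yes	Yes	No	Yes
P	Yes	Yes	Yes	No	No
M	Yes	Yes	No	Yes	No
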