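sample_id	label_species	catch_area	processing_level	product_type	realtime_pcr	seq_id_1	seq_id_2
1415	Cod	Atlantic	2	breaded fillet	Negative	Gadus macrocephalus	Gadus macrocephalus
1426	Cod	Atlantic	2	breaded fillet	Negative	Gadus macrocephalus	Gadus macrocephalus
1446	Cod	Atlantic	2	breaded fillet	Negative	Gadus macrocephalus	Gadus macrocephalus
1747	Cod	Atlantic	4	precooked meal	Negative	Gadus macrocephalus	Gadus macrocephalus
1889	Cod	Atlantic	4	precooked meal	Negative	Gadus macrocephalus	Gadus macrocephalus
1975	Cod	Atlantic	2	breaded fillet	Negative	Gadus macrocephalus	Gadus macrocephalus
1886	Cod	NA	5	fish cakes	Inconclusive	Gadus morhua	Melanogrammus aeglefinus
1765	Cod	NA	5	fish cakes	Melanogrammus aeglefinus	Melanogrammus aeglefinus	Melanogrammus aeglefinus
1892	Cod	NA	3	fish fingers	Gadus morhua	Gadus chalcogrammus	Gadus morhua
1470	Haddock	Atlantic	4	precooked meal	Gadus morhua	Gadus morhua	Gadus morhua
1812	Haddock	Atlantic	5	fish cakes	Gadus morhua	Gadus morhua	Gadus morhua
1888	Haddock	Atlantic	4	precooked meal	Gadus morhua	Gadus morhua	Gadus morhua
1977	Haddock	Atlantic	2	breaded fillet	Gadus morhua	Gadus morhua	Gadus morhua
1989	Haddock	Atlantic	4	precooked meal	Gadus morhua	Gadus morhua	Gadus morhua
1868	Haddock	Atlantic	4	precooked meal	Gadus morhua	Gadus morhua	Gadus morhua
1851	Haddock	Atlantic	4	precooked meal	Negative	Gadus macrocephalus	Gadus macrocephalus
1452	Haddock	Atlantic	5	fish cakes	Inconclusive	Gadus morhua	Melanogrammus aeglefinus
1847	Haddock	Atlantic	5	fish cakes	Inconclusive	Gadus morhua	Melanogrammus aeglefinus
1763	Alaskan Pollack	Pacific	5	fish cakes	Negative	Pangasius hypophthalamus	Gadus chalcogrammus
1813	Hake (M. capensis)	NA	2	breaded fillet	Negative	Merluccius paradoxus	Merluccius paradoxus
1848	Whiting	NA	4	precooked meal	Inconclusive	Micromesistius poutassou	Micromesistius poutassou
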