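species,clade,n,n_left,n_right,n_ambi,mean_hi,mean_abs_hi,p_direction,p_distribution
Ateles fusciceps,Platyrrhini,46,20,22,4,0.063,0.798,0.618,0.288
Ateles geoffroyi,Platyrrhini,23,10,11,2,0.061,0.829,0.748,0.536
Ateles hybridus,Platyrrhini,18,13,5,0,-0.377,0.917,0.086,0.018
Cercocebus torquatus,Cercopithecoidea,31,13,11,7,-0.029,0.665,0.832,0.836
Cercopithecus diana,Cercopithecoidea,20,7,10,3,0.178,0.755,0.339,0.836
Cercopithecus neglectus,Cercopithecoidea,25,14,7,4,-0.258,0.621,0.061,0.140
Gorilla gorilla,Hominoidea,76,17,41,18,0.248,0.541,<0.001,0.007
Homo sapiens,Hominoidea,127,12,111,4,0.761,0.943,<0.001,<0.001
Hylobates lar,Hominoidea,36,17,16,3,-0.011,0.614,0.924,0.182
Hylobates moloch,Hominoidea,22,11,8,3,-0.115,0.799,0.540,0.552
Leontopithecus chrysomelas,Platyrrhini,30,7,12,11,0.151,0.514,0.171,0.012
Leontopithecus chrysopygus,Platyrrhini,15,3,4,8,0.039,0.350,0.744,0.001
Leontopithecus rosalia,Platyrrhini,28,10,8,10,0.022,0.502,0.850,0.033
Macaca fascicularis,Cercopithecoidea,20,8,10,2,-0.036,0.684,0.835,0.233
Macaca nemestrina,Cercopithecoidea,29,9,11,9,0.035,0.527,0.768,0.750
Macaca silenus,Cercopithecoidea,35,14,9,12,-0.051,0.467,0.596,0.328
Macaca sylvanus,Cercopithecoidea,24,12,10,2,-0.025,0.670,0.873,0.129
Macaca tonkeana,Cercopithecoidea,14,5,3,6,-0.057,0.543,0.753,0.291
Mandrillus sphinx,Cercopithecoidea,32,6,10,16,0.034,0.389,0.701,0.006
Nomascus gabriellae,Hominoidea,10,5,2,3,-0.173,0.618,0.465,0.436
Nomascus leucogenys,Hominoidea,26,9,11,6,-0.031,0.555,0.818,0.869
Pan paniscus,Hominoidea,118,50,51,17,0.044,0.529,0.431,0.237
Pan troglodytes,Hominoidea,536,155,266,115,0.133,0.507,<0.001,<0.001
Papio anubis,Cercopithecoidea,84,27,41,16,0.108,0.527,0.102,0.073
Papio hamadryas,Cercopithecoidea,24,6,7,11,0.066,0.408,0.533,0.082
Pithecia pithecia,Platyrrhini,7,5,2,0,-0.385,0.934,0.312,0.221
Pongo sp.,Hominoidea,47,27,9,11,-0.225,0.487,0.006,0.012
Pygathrix cinerea,Cercopithecoidea,18,6,10,2,0.165,0.499,0.268,0.196
Rhinopithecus roxellana,Cercopithecoidea,24,17,7,0,-0.319,0.729,0.040,<0.001
Saimiri sciureus,Platyrrhini,36,21,14,1,-0.119,0.757,0.382,0.031
Sapajus apella,Platyrrhini,25,11,10,4,-0.028,0.687,0.854,0.961
Sapajus flavius,Platyrrhini,21,10,7,4,-0.130,0.769,0.495,0.755
Sapajus xanthosternos,Platyrrhini,34,14,15,5,0.089,0.677,0.492,0.906
Semnopithecus entellus,Cercopithecoidea,30,15,8,7,-0.184,0.560,0.110,0.315
Symphalangus syndactylus,Hominoidea,31,11,9,11,-0.048,0.482,0.663,0.118
Theropithecus gelada,Cercopithecoidea,38,6,6,26,0.053,0.257,0.326,<0.001
Trachypithecus auratus,Cercopithecoidea,8,5,3,0,-0.256,0.984,0.499,0.176
Trachypithecus hatinhensis,Cercopithecoidea,18,11,7,0,-0.248,0.817,0.219,0.023
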