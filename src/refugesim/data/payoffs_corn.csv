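crop,mode,focal_species,focal_genotype,opponent_species,opponent_genotype,rho_s,provenance,source_quote
corn,inter,HA,SS,SF,RR,0.00,printed,corn interspecific assay Ha-SS vs Sf-RR: no H. armigera survivors
corn,inter,SF,RR,HA,SS,0.25,printed,corn interspecific assay Ha-SS vs Sf-RR: S. frugiperda RR survival
corn,inter,HA,RR,SF,SS,0.30,printed,corn interspecific assay Ha-RR vs Sf-SS: H. armigera RR survival
corn,inter,SF,SS,HA,RR,0.55,printed,corn interspecific assay Ha-RR vs Sf-SS: S. frugiperda SS survival
corn,intra,HA,SS,HA,SS,0.25,printed,corn intraspecific assay Ha-SS vs Ha-SS
corn,intra,HA,RR,HA,SS,0.125,printed,corn intraspecific assay Ha-RR vs Ha-SS: H. armigera RR survival
corn,intra,HA,RR,HA,RR,0.38,printed,corn intraspecific assay Ha-RR vs Ha-RR
corn,intra,SF,SS,SF,SS,0.325,printed,corn intraspecific assay Sf-SS vs Sf-SS
corn,intra,SF,RR,SF,SS,0.500,printed,corn intraspecific assay Sf-RR vs Sf-SS: S. frugiperda RR survival
corn,intra,SF,RR,SF,RR,0.475,printed,corn intraspecific assay Sf-RR vs Sf-RR
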