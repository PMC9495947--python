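crop,mode,focal_species,focal_genotype,opponent_species,opponent_genotype,rho_s,provenance,source_quote
cotton,inter,SF,SS,HA,SS,0.60,printed,cotton interspecific assay Ha-SS vs Sf-SS: S. frugiperda 5-day survival
cotton,inter,HA,SS,SF,SS,0.15,printed,cotton interspecific assay Ha-SS vs Sf-SS: H. armigera 5-day survival
cotton,inter,SF,SS,HA,RR,0.57,printed,cotton interspecific assay Ha-RR vs Sf-SS: S. frugiperda 5-day survival
cotton,inter,SF,RR,HA,SS,0.20,printed,cotton interspecific assay Ha-SS vs Sf-RR: S. frugiperda 5-day survival
cotton,inter,HA,SS,SF,RR,0.00,printed,cotton interspecific assay Ha-SS vs Sf-RR: no H. armigera survivors
cotton,intra,HA,SS,HA,SS,0.375,printed,cotton intraspecific assay Ha-SS vs Ha-SS
cotton,intra,HA,RR,HA,SS,0.175,printed,cotton intraspecific assay Ha-RR vs Ha-SS: H. armigera RR survival
cotton,intra,HA,RR,HA,RR,0.40,printed,cotton intraspecific assay Ha-RR vs Ha-RR
cotton,intra,SF,RR,SF,SS,0.175,printed,cotton intraspecific assay Sf-RR vs Sf-SS: S. frugiperda RR survival
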