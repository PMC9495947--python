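crop,mode,focal_species,focal_genotype,opponent_species,opponent_genotype,rho_s,provenance,source_quote
soybean,inter,HA,SS,SF,SS,0.85,printed,soybean interspecific assay Ha-SS vs Sf-SS: H. armigera 5-day survival
soybean,inter,SF,SS,HA,SS,0.55,printed,soybean interspecific assay Ha-SS vs Sf-SS: S. frugiperda 5-day survival
soybean,inter,SF,RR,HA,RR,0.25,printed,soybean interspecific assay Ha-RR vs Sf-RR: S. frugiperda RR survival
soybean,intra,HA,SS,HA,SS,0.725,printed,soybean intraspecific assay Ha-SS vs Ha-SS
soybean,intra,HA,RR,HA,SS,0.475,printed,soybean intraspecific assay Ha-RR vs Ha-SS: H. armigera RR survival
soybean,intra,HA,RR,HA,RR,0.55,printed,soybean intraspecific assay Ha-RR vs Ha-RR
soybean,intra,SF,SS,SF,SS,0.20,printed,soybean intraspecific assay Sf-SS vs Sf-SS
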