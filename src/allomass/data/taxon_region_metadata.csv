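taxon,region,n_individuals,n_families,length_min,length_max,mass_min,mass_max
Araneae,temperate,519,16,1.01,12.26,0.15,212.78
Araneae,tropical,1081,27,0.78,25.71,0.01,5108.57
Coleoptera,temperate,382,15,1.66,35.10,0.33,1067.93
Coleoptera,tropical,281,21,1.10,43.42,0.05,3698.96
Dermaptera,temperate,60,2,3.00,13.96,2.13,72.06
Dermaptera,tropical,130,3,1.87,18.71,0.01,92.57
Dictyoptera,tropical,247,6,1.69,65.07,0.42,1060.93
Diptera,temperate,504,31,1.49,16.82,0.07,74.50
Diptera,tropical,189,28,1.58,23.61,0.07,165.17
Geophilomorpha,tropical,13,2,7.47,33.54,0.29,21.03
Hemiptera,temperate,598,14,1.31,12.05,0.27,146.90
Hemiptera,tropical,454,35,0.95,23.76,0.05,261.53
Hymenoptera,temperate,222,14,1.70,22.26,0.06,835.43
Hymenoptera,tropical,371,23,0.62,31.88,0.01,1664.61
Isopoda,temperate,88,6,2.45,16.16,0.81,181.27
Isopoda,tropical,88,3,2.45,16.16,0.22,189.52
Lepidoptera,temperate,29,4,3.56,16.23,1.67,91.02
Lepidoptera,tropical,87,9,3.23,27.43,0.56,908.65
Lithobiomorpha,temperate,161,1,2.77,23.63,0.65,170.65
Lithobiomorpha,tropical,60,1,2.22,51.21,0.01,439.53
Neuroptera,temperate,21,2,3.79,11.34,2.61,17.44
Neuroptera,tropical,18,4,3.26,27.29,1.33,144.05
Odonata,tropical,19,2,23.37,54.83,44.96,367.32
Opiliones,temperate,89,3,0.93,7.53,0.81,95.02
Opiliones,tropical,24,3,1.09,10.09,0.40,165.61
Orthoptera,temperate,35,2,3.79,24.28,3.81,417.84
Orthoptera,tropical,277,6,1.28,68.12,0.14,3895.10
Polydesmida,temperate,12,1,9.21,19.95,9.24,67.25
Polydesmida,tropical,80,1,4.02,32.55,0.05,205.02
Pseudoscorpionida,tropical,36,2,0.95,4.16,0.16,2.12
Psocoptera,tropical,26,3,1.12,2.92,0.11,8.00
Scolopendromorpha,tropical,11,2,4.83,41.84,0.88,276.18
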