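model_id,taxon,region,intercept,slope_length,slope_width,sig_intercept,sig_length,sig_width
LWTR,Araneae,temperate,-0.281,1.368,1.480,***,***,***
LWTR,Coleoptera,temperate,-0.286,0.840,1.954,***,***,***
LWTR,Dermaptera,temperate,-0.369,1.180,1.580,*,***,***
LWTR,Diptera,temperate,-0.309,0.997,1.595,***,***,***
LWTR,Hemiptera,temperate,-0.420,1.177,1.431,***,***,***
LWTR,Hymenoptera,temperate,-0.450,1.144,1.724,***,***,***
LWTR,Isopoda,temperate,-0.453,0.898,1.756,**,**,***
LWTR,Lepidoptera,temperate,-0.158,0.613,2.244,,***,***
LWTR,Lithobiomorpha,temperate,-0.549,1.416,1.543,***,***,***
LWTR,Neuroptera,temperate,0.575,-0.042,2.535,*,,***
LWTR,Opiliones,temperate,-0.241,1.353,1.377,***,***,***
LWTR,Orthoptera,temperate,0.136,0.823,1.713,,**,***
LWTR,Polydesmida,temperate,-1.400,2.443,0.215,*,***,
LWTR,Araneae,tropical,-0.464,1.539,1.448,***,***,***
LWTR,Coleoptera,tropical,-0.523,1.125,1.820,***,***,***
LWTR,Dermaptera,tropical,-0.605,1.301,1.704,***,***,***
LWTR,Dictyoptera,tropical,-0.326,0.845,1.764,***,***,***
LWTR,Diptera,tropical,-0.441,1.199,1.399,***,***,***
LWTR,Geophilomorpha,tropical,-0.419,0.964,1.766,,*,***
LWTR,Hemiptera,tropical,-0.529,1.337,1.260,***,***,***
LWTR,Hymenoptera,tropical,-0.463,1.070,1.798,***,***,***
LWTR,Isopoda,tropical,-0.800,1.646,1.154,***,***,***
LWTR,Lepidoptera,tropical,-0.256,0.795,2.036,*,***,***
LWTR,Lithobiomorpha,tropical,-1.350,2.112,0.742,***,***,
LWTR,Neuroptera,tropical,-0.727,1.506,1.344,***,***,***
LWTR,Odonata,tropical,-0.513,0.923,1.635,,,
LWTR,Opiliones,tropical,-0.384,2.301,0.370,**,***,
LWTR,Orthoptera,tropical,-0.117,1.001,1.673,**,***,***
LWTR,Polydesmida,tropical,-0.179,1.012,2.191,,***,***
LWTR,Pseudoscorpionida,tropical,-0.801,1.750,0.300,***,***,*
LWTR,Psocoptera,tropical,-0.936,2.294,0.666,***,***,
LWTR,Scolopendromorpha,tropical,-0.962,1.669,1.278,*,***,**
LWT,Araneae,,-0.410,1.486,1.492,***,***,***
LWT,Coleoptera,,-0.419,1.001,1.880,***,***,***
LWT,Dermaptera,,-0.187,0.747,2.228,**,***,***
LWT,Dictyoptera,,-0.326,0.845,1.764,***,***,***
LWT,Diptera,,-0.375,1.107,1.498,***,***,***
LWT,Geophilomorpha,,-0.419,0.964,1.766,,*,***
LWT,Hemiptera,,-0.472,1.253,1.362,***,***,***
LWT,Hymenoptera,,-0.429,1.050,1.801,***,***,***
LWT,Isopoda,,-0.690,1.387,1.393,***,***,***
LWT,Lepidoptera,,-0.253,0.785,2.051,**,***,***
LWT,Lithobiomorpha,,-0.327,1.083,2.058,**,***,***
LWT,Neuroptera,,-0.515,1.251,1.533,***,***,***
LWT,Odonata,,-0.513,0.923,1.635,,,
LWT,Opiliones,,-0.243,1.442,1.262,***,***,***
LWT,Orthoptera,,-0.095,0.968,1.730,*,***,***
LWT,Polydesmida,,-0.417,1.245,1.809,*,***,***
LWT,Pseudoscorpionida,,-0.801,1.750,0.300,***,***,*
LWT,Psocoptera,,-0.936,2.294,0.666,***,***,
LWT,Scolopendromorpha,,-0.962,1.669,1.278,*,***,***
LWR,,temperate,-0.285,1.040,1.585,***,***,***
LWR,,tropical,-0.371,1.087,1.647,***,***,***
LW,,,-0.340,1.070,1.634,***,***,***
LTR,Araneae,temperate,-0.733,2.623,,***,***,
LTR,Coleoptera,temperate,-0.938,2.501,,***,***,
LTR,Dermaptera,temperate,-0.947,2.337,,***,***,
LTR,Diptera,temperate,-1.057,2.489,,***,***,
LTR,Hemiptera,temperate,-0.902,2.386,,***,***,
LTR,Hymenoptera,temperate,-1.486,3.018,,***,***,
LTR,Isopoda,temperate,-1.292,2.950,,***,***,
LTR,Lepidoptera,temperate,-1.274,2.505,,***,***,
LTR,Lithobiomorpha,temperate,-1.671,2.780,,***,***,
LTR,Neuroptera,temperate,0.152,0.888,,***,,
LTR,Opiliones,temperate,-0.364,2.379,,,***,
LTR,Orthoptera,temperate,-0.640,2.267,,***,***,
LTR,Polydesmida,temperate,-1.519,2.595,,*,***,
LTR,Araneae,tropical,-0.862,2.611,,***,***,
LTR,Coleoptera,tropical,-1.123,2.616,,***,***,
LTR,Dermaptera,tropical,-1.775,2.929,,***,***,
LTR,Dictyoptera,tropical,-0.644,1.913,,***,***,
LTR,Diptera,tropical,-0.973,2.271,,***,***,
LTR,Geophilomorpha,tropical,-2.917,2.837,,***,***,
LTR,Hemiptera,tropical,-0.813,2.189,,***,***,
LTR,Hymenoptera,tropical,-1.422,2.792,,***,***,
LTR,Isopoda,tropical,-1.268,2.839,,***,***,
LTR,Lepidoptera,tropical,-1.425,2.637,,***,***,
LTR,Lithobiomorpha,tropical,-1.884,2.701,,***,***,
LTR,Neuroptera,tropical,-0.884,2.112,,***,***,
LTR,Odonata,tropical,-0.499,1.703,,,***,
LTR,Opiliones,tropical,-0.453,2.648,,***,***,
LTR,Orthoptera,tropical,-0.775,2.205,,***,***,
LTR,Polydesmida,tropical,-1.825,2.726,,***,***,
LTR,Pseudoscorpionida,tropical,-0.942,2.015,,***,***,
LTR,Psocoptera,tropical,-1.154,2.710,,***,***,
LTR,Scolopendromorpha,tropical,-2.084,2.702,,***,***,
LT,Araneae,,-0.830,2.637,,***,***,
LT,Coleoptera,,-1.053,2.592,,***,***,
LT,Dermaptera,,-1.316,2.529,,***,***,
LT,Dictyoptera,,-0.644,1.913,,***,***,
LT,Diptera,,-1.032,2.430,,,***,
LT,Geophilomorpha,,-2.917,2.837,,***,***,
LT,Hemiptera,,-0.817,2.237,,***,***,
LT,Hymenoptera,,-1.401,2.809,,***,***,
LT,Isopoda,,-1.322,2.967,,***,***,
LT,Lepidoptera,,-1.381,2.599,,***,***,
LT,Lithobiomorpha,,-1.888,2.934,,***,***,
LT,Neuroptera,,-0.871,2.010,,***,***,
LT,Odonata,,-0.499,1.703,,,***,
LT,Opiliones,,-0.385,2.439,,***,***,
LT,Orthoptera,,-0.791,2.245,,***,***,
LT,Polydesmida,,-1.986,2.944,,***,***,
LT,Psocoptera,,-1.154,2.710,,***,***,
LT,Pseudoscorpionida,,-0.942,2.015,,***,***,
LT,Scolopendromorpha,,-2.084,2.702,,***,***,
LR,,temperate,-0.736,2.191,,***,***,
LR,,tropical,-0.826,2.159,,***,***,
L,,,-0.792,2.181,,***,***,
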