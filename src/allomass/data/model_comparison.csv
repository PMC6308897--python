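rank,model_id,formula,predictors,bic,delta_bic,bic_weight,r2,prediction_error
1,LWTR,log10(mass) ~ TaxReg x (log10(length) + log10(width)),"length;width;taxon;region",-7797.96,0,1,0.972,0.016
2,LWT,log10(mass) ~ taxon x (log10(length) + log10(width)),"length;width;taxon",-7601.34,196.62,0,0.970,0.017
3,LWR,log10(mass) ~ region x (log10(length) + log10(width)),"length;width;region",-4307.07,3490.89,0,0.945,0.029
4,LW,log10(mass) ~ log10(length) + log10(width),"length;width",-4213.35,3585.61,0,0.944,0.030
5,LTR,log10(mass) ~ TaxReg x log10(length),"length;taxon;region",-1038.94,6759.02,0,0.914,0.046
6,LT,log10(mass) ~ taxon x log10(length),"length;taxon",-803.49,6994.47,0,0.910,0.049
7,LR,log10(mass) ~ region x log10(length),"length;region",2909.16,10707.12,0,0.824,0.093
8,L,log10(mass) ~ log10(length),"length",3096.11,10894.07,0,0.818,0.096
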