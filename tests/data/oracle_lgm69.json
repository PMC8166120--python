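{"loglik_cond":18.092999355879,"loglik_sat_cond":20.725243319882,"loglik_baseline_cond":6.833683900042,"estimates":{"I~1":0.3076179768561,"S~1":0.0475922975562,"I~mfq_fof":0.008638292353354,"S~mfq_fof":-0.07540540621074,"I~age_c":0.007608954247048,"S~age_c":3.125677209532e-05,"I~~I":0.01968276075541,"S~~S":0.01012380516937,"I~~S":-0.005012936889592,"y1~~y1":0.01709566396297,"y2~~y2":0.02777194317072,"y3~~y3":0.04538190800692},"std":{"I~1":2.057681904222,"S~1":0.3980447265887,"I~mfq_fof":0.04948511869683,"S~mfq_fof":-0.5401046031645,"I~age_c":0.3449606342057,"S~age_c":0.001771810894641,"I~~I":0.8806818927296,"S~~S":0.7081645546701,"I~~S":-0.2804490461503,"y1~~y1":0.4334037823563,"y2~~y2":0.5155095964265,"y3~~y3":0.4370965024477},"fit":{"chi2":5.264487928006,"df":3,"cfi":0.8794402597708,"rmsea":0.1045923286277,"rmsea_ci_lower":0,"rmsea_ci_upper":0.2722943797745,"srmr":0.08835564466234}}
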