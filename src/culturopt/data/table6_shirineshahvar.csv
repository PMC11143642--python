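cultivar,model,trait,subset,RRMSE_pct,RMSE,MAE,MAPE_pct,R2,R
Shirineshahvar,XGB,LN,train,6.63,1.156,0.932,5.64,0.616,0.785
Shirineshahvar,RF,LN,train,4.86,0.849,0.702,4.11,0.792,0.89
Shirineshahvar,SVR,LN,train,5.04,0.879,0.738,4.33,0.783,0.885
Shirineshahvar,ENMLR,LN,train,7.43,1.297,0.957,5.96,0.516,0.718
Shirineshahvar,ESR,LN,train,4.91,0.857,0.706,4.14,0.789,0.888
Shirineshahvar,XGB,LN,test,6.66,1.157,0.896,5.67,0.74,0.86
Shirineshahvar,RF,LN,test,4.68,0.812,0.65,3.84,0.863,0.929
Shirineshahvar,SVR,LN,test,4.67,0.811,0.653,3.92,0.863,0.929
Shirineshahvar,ENMLR,LN,test,8.4,1.457,1.081,7.03,0.593,0.77
Shirineshahvar,ESR,LN,test,4.64,0.805,0.644,3.81,0.865,0.93
Shirineshahvar,XGB,PR,train,19.19,0.496,0.358,17.2,0.65,0.806
Shirineshahvar,RF,PR,train,20.49,0.53,0.365,19.65,0.627,0.792
Shirineshahvar,SVR,PR,train,20.0,0.517,0.355,18.39,0.654,0.809
Shirineshahvar,ENMLR,PR,train,22.99,0.594,0.463,23.54,0.503,0.709
Shirineshahvar,ESR,PR,train,19.04,0.492,0.375,19.26,0.656,0.81
Shirineshahvar,XGB,PR,test,21.86,0.546,0.407,20.98,0.63,0.794
Shirineshahvar,RF,PR,test,23.92,0.598,0.431,25.86,0.59,0.768
Shirineshahvar,SVR,PR,test,22.35,0.559,0.398,22.64,0.638,0.799
Shirineshahvar,ENMLR,PR,test,24.0,0.6,0.503,28.14,0.584,0.764
Shirineshahvar,ESR,PR,test,21.07,0.526,0.406,22.45,0.677,0.823
Shirineshahvar,XGB,ES,train,11.08,5.825,4.768,9.2,0.354,0.595
Shirineshahvar,RF,ES,train,10.58,5.563,4.525,8.71,0.413,0.643
Shirineshahvar,SVR,ES,train,10.86,5.706,4.866,9.48,0.387,0.622
Shirineshahvar,ENMLR,ES,train,12.35,6.49,5.179,9.98,0.307,0.554
Shirineshahvar,XGB,ES,test,11.08,5.769,4.821,9.46,0.388,0.623
Shirineshahvar,RF,ES,test,11.26,5.862,4.834,9.52,0.361,0.601
Shirineshahvar,SVR,ES,test,11.73,6.107,5.233,10.37,0.338,0.581
Shirineshahvar,ENMLR,ES,test,12.49,6.501,5.222,10.26,0.375,0.612
Shirineshahvar,ESR,ES,test,11.05,5.754,4.752,9.44,0.391,0.625
Shirineshahvar,XGB,SL,train,5.14,0.084,0.063,4.07,0.845,0.919
Shirineshahvar,RF,SL,train,4.58,0.075,0.058,3.76,0.87,0.933
Shirineshahvar,SVR,SL,train,4.67,0.076,0.059,3.84,0.867,0.931
Shirineshahvar,ENMLR,SL,train,6.03,0.098,0.073,4.72,0.774,0.88
Shirineshahvar,ESR,SL,train,4.75,0.077,0.058,3.78,0.861,0.928
Shirineshahvar,XGB,SL,test,4.97,0.081,0.063,3.96,0.845,0.919
Shirineshahvar,RF,SL,test,4.54,0.074,0.057,3.64,0.867,0.931
Shirineshahvar,SVR,SL,test,4.64,0.075,0.055,3.52,0.857,0.926
Shirineshahvar,ENMLR,SL,test,6.6,0.108,0.081,5.11,0.717,0.847
Shirineshahvar,ESR,SL,test,4.45,0.072,0.055,3.48,0.87,0.933
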