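cultivar,model,trait,subset,RRMSE_pct,RMSE,MAE,MAPE_pct,R2,R
Atabaki,XGB,LN,train,6.07,1.018,0.817,4.92,0.356,0.597
Atabaki,RF,LN,train,5.67,0.952,0.774,4.66,0.35,0.592
Atabaki,SVR,LN,train,5.77,0.969,0.803,4.83,0.333,0.577
Atabaki,ENMLR,LN,train,6.21,1.042,0.836,5.03,0.222,0.471
Atabaki,ESR,LN,train,5.82,0.976,0.77,4.65,0.317,0.563
Atabaki,XGB,LN,test,6.06,1.019,0.781,4.59,0.296,0.544
Atabaki,RF,LN,test,5.67,0.953,0.728,4.3,0.381,0.617
Atabaki,SVR,LN,test,5.7,0.958,0.761,4.51,0.381,0.617
Atabaki,ENMLR,LN,test,6.5,1.094,0.82,4.81,0.185,0.43
Atabaki,ESR,LN,test,5.48,0.922,0.698,4.15,0.425,0.652
Atabaki,XGB,PR,train,20.42,0.634,0.526,20.98,0.254,0.504
Atabaki,RF,PR,train,19.51,0.606,0.523,20.74,0.421,0.649
Atabaki,SVR,PR,train,19.56,0.607,0.549,21.05,0.412,0.642
Atabaki,ENMLR,PR,train,24.87,0.772,0.574,25.09,0.264,0.514
Atabaki,ESR,PR,train,19.88,0.617,0.552,21.95,0.394,0.628
Atabaki,XGB,PR,test,20.43,0.635,0.528,20.56,0.358,0.598
Atabaki,RF,PR,test,20.6,0.64,0.555,21.27,0.347,0.589
Atabaki,SVR,PR,test,21.73,0.675,0.596,22.08,0.3,0.548
Atabaki,ENMLR,PR,test,24.85,0.773,0.595,24.72,0.319,0.565
Atabaki,ESR,PR,test,20.26,0.63,0.516,21.77,0.376,0.613
Atabaki,XGB,ES,train,7.19,6.057,4.553,5.33,0.581,0.762
Atabaki,RF,ES,train,6.0,5.051,3.15,3.69,0.707,0.841
Atabaki,SVR,ES,train,6.26,5.275,3.255,3.71,0.697,0.835
Atabaki,ENMLR,ES,train,7.95,6.692,5.298,6.15,0.49,0.7
Atabaki,ESR,ES,train,6.1,5.136,3.299,3.9,0.699,0.836
Atabaki,XGB,ES,test,8.27,7.045,5.437,6.34,0.484,0.696
Atabaki,RF,ES,test,6.62,5.64,3.442,3.82,0.674,0.821
Atabaki,SVR,ES,test,6.94,5.917,3.623,4.04,0.667,0.817
Atabaki,ENMLR,ES,test,8.2,6.982,5.705,6.57,0.501,0.708
Atabaki,ESR,ES,test,6.45,5.494,3.328,3.82,0.687,0.829
Atabaki,XGB,SL,train,21.19,0.587,0.413,13.87,0.789,0.888
Atabaki,RF,SL,train,8.46,0.234,0.153,5.25,0.966,0.983
Atabaki,SVR,SL,train,8.57,0.237,0.148,5.08,0.964,0.982
Atabaki,ENMLR,SL,train,24.0,0.665,0.47,16.18,0.729,0.854
Atabaki,ESR,SL,train,11.05,0.306,0.214,7.66,0.953,0.976
Atabaki,XGB,SL,test,20.91,0.596,0.469,16.22,0.759,0.871
Atabaki,RF,SL,test,11.07,0.316,0.205,6.35,0.935,0.967
Atabaki,SVR,SL,test,11.36,0.324,0.205,6.38,0.933,0.966
Atabaki,ENMLR,SL,test,21.16,0.617,0.498,17.88,0.729,0.854
Atabaki,ESR,SL,test,10.6,0.302,0.199,6.78,0.935,0.967
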