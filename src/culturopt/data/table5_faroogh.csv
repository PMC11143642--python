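cultivar,model,trait,subset,RRMSE_pct,RMSE,MAE,MAPE_pct,R2,R
Faroogh,XGB,LN,train,5.33,1.079,0.801,3.89,0.545,0.738
Faroogh,RF,LN,train,4.78,0.969,0.749,3.65,0.645,0.803
Faroogh,SVR,LN,train,4.52,0.915,0.692,3.39,0.677,0.823
Faroogh,ENMLR,LN,train,5.78,1.17,0.918,4.46,0.462,0.68
Faroogh,ESR,LN,train,4.49,0.909,0.699,3.43,0.676,0.822
Faroogh,XGB,LN,test,6.01,1.225,0.926,4.51,0.498,0.706
Faroogh,RF,LN,test,5.11,1.041,0.834,4.05,0.671,0.819
Faroogh,SVR,LN,test,4.85,0.989,0.801,3.92,0.684,0.827
Faroogh,ENMLR,LN,test,6.6,1.345,1.06,5.17,0.393,0.627
Faroogh,ESR,LN,test,4.6,0.938,0.73,3.58,0.711,0.843
Faroogh,XGB,PR,train,12.86,0.562,0.394,11.82,0.212,0.46
Faroogh,RF,PR,train,12.82,0.461,0.399,11.95,0.22,0.469
Faroogh,SVR,PR,train,13.42,0.483,0.449,13.41,0.172,0.415
Faroogh,ENMLR,PR,train,13.54,0.487,0.432,12.97,0.127,0.356
Faroogh,ESR,PR,train,12.86,0.462,0.394,11.87,0.213,0.462
Faroogh,XGB,PR,test,14.29,0.518,0.427,13.3,0.182,0.427
Faroogh,RF,PR,test,14.17,0.514,0.43,13.37,0.199,0.446
Faroogh,SVR,PR,test,14.54,0.527,0.47,14.63,0.208,0.456
Faroogh,ENMLR,PR,test,14.38,0.521,0.444,13.95,0.186,0.431
Faroogh,ESR,PR,test,14.14,0.512,0.418,13.1,0.199,0.446
Faroogh,XGB,ES,train,6.26,5.456,4.646,5.42,0.514,0.717
Faroogh,RF,ES,train,5.42,4.72,4.054,4.76,0.637,0.798
Faroogh,SVR,ES,train,5.64,4.912,4.366,5.01,0.634,0.796
Faroogh,ENMLR,ES,train,6.87,5.981,5.188,6.0,0.417,0.646
Faroogh,ESR,ES,train,5.47,4.769,4.094,4.82,0.63,0.794
Faroogh,XGB,ES,test,6.32,5.516,4.582,5.4,0.514,0.717
Faroogh,RF,ES,test,4.92,4.291,3.778,4.46,0.699,0.836
Faroogh,SVR,ES,test,5.07,4.424,4.025,4.61,0.711,0.843
Faroogh,ENMLR,ES,test,6.67,5.822,4.92,5.71,0.448,0.669
Faroogh,ESR,ES,test,4.84,4.228,3.711,4.39,0.709,0.842
Faroogh,XGB,SL,train,11.72,0.375,0.279,8.49,0.699,0.836
Faroogh,RF,SL,train,8.46,0.271,0.184,5.4,0.843,0.918
Faroogh,SVR,SL,train,8.95,0.286,0.199,6.02,0.828,0.91
Faroogh,ENMLR,SL,train,12.54,0.401,0.295,8.99,0.654,0.809
Faroogh,ESR,SL,train,8.84,0.283,0.19,5.66,0.83,0.911
Faroogh,XGB,SL,test,13.77,0.449,0.339,10.16,0.707,0.841
Faroogh,RF,SL,test,9.94,0.259,0.177,4.88,0.937,0.968
Faroogh,SVR,SL,test,7.33,0.239,0.175,5.11,0.927,0.963
Faroogh,ENMLR,SL,test,15.4,0.503,0.38,11.39,0.624,0.79
Faroogh,ESR,SL,test,7.27,0.237,0.164,4.66,0.941,0.97
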