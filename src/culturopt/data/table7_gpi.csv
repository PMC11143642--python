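cultivar,trait,model,gpi,rank
Atabaki,LN,XGB,-1.674,4
Atabaki,LN,RF,0.647,2
Atabaki,LN,SVR,0.000,3
Atabaki,LN,ENMLR,-4.171,5
Atabaki,LN,ESR,1.829,1
Faroogh,LN,XGB,-2.562,4
Faroogh,LN,RF,0.000,3
Faroogh,LN,SVR,0.525,2
Faroogh,LN,ENMLR,-4.688,5
Faroogh,LN,ESR,1.312,1
Shirineshahvar,LN,XGB,-3.040,4
Shirineshahvar,LN,RF,0.032,2
Shirineshahvar,LN,SVR,0.004,3
Shirineshahvar,LN,ENMLR,-5.911,5
Shirineshahvar,LN,ESR,0.089,1
Atabaki,PR,XGB,0.980,2
Atabaki,PR,RF,0.738,3
Atabaki,PR,SVR,-2.326,4
Atabaki,PR,ENMLR,-3.801,5
Atabaki,PR,ESR,1.383,1
Faroogh,PR,XGB,-1.199,3
Faroogh,PR,RF,0.567,2
Faroogh,PR,SVR,-2.121,4
Faroogh,PR,ENMLR,-2.104,5
Faroogh,PR,ESR,1.182,1
Shirineshahvar,PR,XGB,0.574,2
Shirineshahvar,PR,RF,-2.616,4
Shirineshahvar,PR,SVR,0.255,3
Shirineshahvar,PR,ENMLR,-3.807,5
Shirineshahvar,PR,ESR,1.911,1
Atabaki,ES,XGB,-4.870,5
Atabaki,ES,RF,0.573,2
Atabaki,ES,SVR,0.000,3
Atabaki,ES,ENMLR,-4.814,4
Atabaki,ES,ESR,0.933,1
Faroogh,ES,XGB,-3.813,4
Faroogh,ES,RF,0.483,2
Faroogh,ES,SVR,0.085,3
Faroogh,ES,ENMLR,-5.240,5
Faroogh,ES,ESR,0.748,1
Shirineshahvar,ES,XGB,0.818,2
Shirineshahvar,ES,RF,-1.501,3
Shirineshahvar,ES,SVR,-2.966,5
Shirineshahvar,ES,ENMLR,-2.507,4
Shirineshahvar,ES,ESR,0.973,1
Atabaki,SL,XGB,-5.158,4
Atabaki,SL,RF,0.108,2
Atabaki,SL,SVR,0.035,3
Atabaki,SL,ENMLR,-5.782,5
Atabaki,SL,ESR,0.180,1
Faroogh,SL,XGB,-4.058,4
Faroogh,SL,RF,0.092,3
Faroogh,SL,SVR,0.405,2
Faroogh,SL,ENMLR,-5.380,5
Faroogh,SL,ESR,0.619,1
Shirineshahvar,SL,XGB,-0.913,4
Shirineshahvar,SL,RF,0.193,2
Shirineshahvar,SL,SVR,0.150,3
Shirineshahvar,SL,ENMLR,-5.487,5
Shirineshahvar,SL,ESR,0.513,1
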