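cultivar,ga3_mg_per_L,zt_mg_per_L,trait,mean,sd,n_rep
Atabaki,0,0,LN,15.75,0.775,20
Atabaki,0,0,PR,2.69,0.479,20
Atabaki,0,0,ES,77.5,2.582,20
Atabaki,0,0,SL,1.72,0.075,20
Atabaki,0,0.25,LN,16.44,0.814,20
Atabaki,0,0.25,PR,3.19,0.403,20
Atabaki,0,0.25,ES,78.44,2.394,20
Atabaki,0,0.25,SL,1.86,0.143,20
Atabaki,0,0.5,LN,16.56,0.814,20
Atabaki,0,0.5,PR,3.0,0.365,20
Atabaki,0,0.5,ES,81.56,7.465,20
Atabaki,0,0.5,SL,2.09,0.128,20
Atabaki,0,0.75,LN,16.94,0.854,20
Atabaki,0,0.75,PR,3.12,0.341,20
Atabaki,0,0.75,ES,82.5,6.831,20
Atabaki,0,0.75,SL,2.21,0.112,20
Atabaki,0.1,0,LN,16.06,1.181,20
Atabaki,0.1,0,PR,2.69,0.479,20
Atabaki,0.1,0,ES,77.5,2.582,20
Atabaki,0.1,0,SL,1.73,0.141,20
Atabaki,0.1,0.25,LN,16.5,1.033,20
Atabaki,0.1,0.25,PR,3.06,0.574,20
Atabaki,0.1,0.25,ES,78.75,2.236,20
Atabaki,0.1,0.25,SL,2.05,0.187,20
Atabaki,0.1,0.5,LN,16.87,0.885,20
Atabaki,0.1,0.5,PR,3.12,0.342,20
Atabaki,0.1,0.5,ES,83.12,8.539,20
Atabaki,0.1,0.5,SL,2.37,0.057,20
Atabaki,0.1,0.75,LN,17.19,0.911,20
Atabaki,0.1,0.75,PR,3.19,0.544,20
Atabaki,0.1,0.75,ES,85.0,8.944,20
Atabaki,0.1,0.75,SL,2.51,0.043,20
Atabaki,0.25,0,LN,15.44,1.153,20
Atabaki,0.25,0,PR,2.62,0.5,20
Atabaki,0.25,0,ES,78.12,2.5,20
Atabaki,0.25,0,SL,2.0,0.229,20
Atabaki,0.25,0.25,LN,18.06,1.181,20
Atabaki,0.25,0.25,PR,2.81,0.403,20
Atabaki,0.25,0.25,ES,82.5,6.831,20
Atabaki,0.25,0.25,SL,2.62,0.155,20
Atabaki,0.25,0.5,LN,17.12,0.885,20
Atabaki,0.25,0.5,PR,2.87,0.342,20
Atabaki,0.25,0.5,ES,83.75,8.062,20
Atabaki,0.25,0.5,SL,2.78,0.113,20
Atabaki,0.25,0.75,LN,17.12,0.957,20
Atabaki,0.25,0.75,PR,3.19,0.403,20
Atabaki,0.25,0.75,ES,86.25,9.574,20
Atabaki,0.25,0.75,SL,2.9,0.125,20
Atabaki,0.5,0,LN,16.06,1.181,20
Atabaki,0.5,0,PR,2.94,0.68,20
Atabaki,0.5,0,ES,77.19,2.562,20
Atabaki,0.5,0,SL,2.97,0.388,20
Atabaki,0.5,0.25,LN,16.75,0.775,20
Atabaki,0.5,0.25,PR,3.12,0.342,20
Atabaki,0.5,0.25,ES,100.0,0.0,20
Atabaki,0.5,0.25,SL,4.05,0.616,20
Atabaki,0.5,0.5,LN,16.87,1.025,20
Atabaki,0.5,0.5,PR,3.56,0.512,20
Atabaki,0.5,0.5,ES,100.0,0.0,20
Atabaki,0.5,0.5,SL,3.99,0.532,20
Atabaki,0.5,0.75,LN,18.25,1.183,20
Atabaki,0.5,0.75,PR,3.56,0.512,20
Atabaki,0.5,0.75,ES,100.0,0.0,20
Atabaki,0.5,0.75,SL,6.75,0.491,20
Faroogh,0,0,LN,19.62,0.619,20
Faroogh,0,0,PR,3.56,0.629,20
Faroogh,0,0,ES,82.5,5.773,20
Faroogh,0,0,SL,2.52,0.192,20
Faroogh,0,0.25,LN,19.62,0.619,20
Faroogh,0,0.25,PR,3.75,0.447,20
Faroogh,0,0.25,ES,83.12,4.787,20
Faroogh,0,0.25,SL,2.85,0.113,20
Faroogh,0,0.5,LN,19.62,0.619,20
Faroogh,0,0.5,PR,3.81,0.403,20
Faroogh,0,0.5,ES,83.12,4.787,20
Faroogh,0,0.5,SL,2.78,0.127,20
Faroogh,0,0.75,LN,19.69,0.479,20
Faroogh,0,0.75,PR,3.81,0.403,20
Faroogh,0,0.75,ES,83.75,5.0,20
Faroogh,0,0.75,SL,2.75,0.169,20
Faroogh,0.1,0,LN,19.56,0.629,20
Faroogh,0.1,0,PR,3.75,0.447,20
Faroogh,0.1,0,ES,83.75,5.0,20
Faroogh,0.1,0,SL,2.79,0.196,20
Faroogh,0.1,0.25,LN,19.62,0.619,20
Faroogh,0.1,0.25,PR,3.75,0.447,20
Faroogh,0.1,0.25,ES,86.25,6.191,20
Faroogh,0.1,0.25,SL,2.92,0.135,20
Faroogh,0.1,0.5,LN,19.94,0.772,20
Faroogh,0.1,0.5,PR,3.81,0.403,20
Faroogh,0.1,0.5,ES,84.37,5.123,20
Faroogh,0.1,0.5,SL,2.86,0.135,20
Faroogh,0.1,0.75,LN,19.62,0.619,20
Faroogh,0.1,0.75,PR,3.81,0.403,20
Faroogh,0.1,0.75,ES,83.75,5.0,20
Faroogh,0.1,0.75,SL,2.79,0.196,20
Faroogh,0.25,0,LN,19.69,0.602,20
Faroogh,0.25,0,PR,3.75,0.447,20
Faroogh,0.25,0,ES,83.75,5.0,20
Faroogh,0.25,0,SL,2.84,0.143,20
Faroogh,0.25,0.25,LN,19.19,0.834,20
Faroogh,0.25,0.25,PR,3.81,0.403,20
Faroogh,0.25,0.25,ES,83.75,5.0,20
Faroogh,0.25,0.25,SL,3.15,0.125,20
Faroogh,0.25,0.5,LN,20.06,0.772,20
Faroogh,0.25,0.5,PR,3.87,0.341,20
Faroogh,0.25,0.5,ES,83.75,5.0,20
Faroogh,0.25,0.5,SL,3.36,0.124,20
Faroogh,0.25,0.75,LN,20.0,0.73,20
Faroogh,0.25,0.75,PR,3.87,0.342,20
Faroogh,0.25,0.75,ES,88.75,7.188,20
Faroogh,0.25,0.75,SL,3.54,0.082,20
Faroogh,0.5,0,LN,19.75,0.447,20
Faroogh,0.5,0,PR,3.69,0.479,20
Faroogh,0.5,0,ES,84.37,5.124,20
Faroogh,0.5,0,SL,2.8,0.087,20
Faroogh,0.5,0.25,LN,22.06,1.569,20
Faroogh,0.5,0.25,PR,3.69,0.479,20
Faroogh,0.5,0.25,ES,100.0,0.0,20
Faroogh,0.5,0.25,SL,4.4,0.647,20
Faroogh,0.5,0.5,LN,22.94,1.769,20
Faroogh,0.5,0.5,PR,3.75,0.447,20
Faroogh,0.5,0.5,ES,100.0,0.0,20
Faroogh,0.5,0.5,SL,4.55,0.544,20
Faroogh,0.5,0.75,LN,23.62,1.67,20
Faroogh,0.5,0.75,PR,4.0,0.0,20
Faroogh,0.5,0.75,ES,100.0,0.0,20
Faroogh,0.5,0.75,SL,4.62,0.506,20
Shirineshahvar,0,0,LN,11.31,1.138,20
Shirineshahvar,0,0,PR,2.31,0.704,20
Shirineshahvar,0,0,ES,43.12,4.787,20
Shirineshahvar,0,0,SL,1.26,0.169,20
Shirineshahvar,0,0.25,LN,15.94,0.929,20
Shirineshahvar,0,0.25,PR,3.12,0.342,20
Shirineshahvar,0,0.25,ES,47.5,5.773,20
Shirineshahvar,0,0.25,SL,1.41,0.063,20
Shirineshahvar,0,0.5,LN,17.37,0.619,20
Shirineshahvar,0,0.5,PR,3.5,0.516,20
Shirineshahvar,0,0.5,ES,50.0,6.324,20
Shirineshahvar,0,0.5,SL,1.54,0.069,20
Shirineshahvar,0,0.75,LN,18.37,0.619,20
Shirineshahvar,0,0.75,PR,3.44,0.512,20
Shirineshahvar,0,0.75,ES,51.87,4.031,20
Shirineshahvar,0,0.75,SL,1.55,0.079,20
Shirineshahvar,0.1,0,LN,16.12,1.025,20
Shirineshahvar,0.1,0,PR,3.44,0.512,20
Shirineshahvar,0.1,0,ES,48.75,6.191,20
Shirineshahvar,0.1,0,SL,1.42,0.082,20
Shirineshahvar,0.1,0.25,LN,17.75,0.774,20
Shirineshahvar,0.1,0.25,PR,3.44,0.512,20
Shirineshahvar,0.1,0.25,ES,52.5,4.472,20
Shirineshahvar,0.1,0.25,SL,1.51,0.051,20
Shirineshahvar,0.1,0.5,LN,18.0,0.816,20
Shirineshahvar,0.1,0.5,PR,3.5,0.516,20
Shirineshahvar,0.1,0.5,ES,52.5,4.472,20
Shirineshahvar,0.1,0.5,SL,1.64,0.04,20
Shirineshahvar,0.1,0.75,LN,18.69,0.793,20
Shirineshahvar,0.1,0.75,PR,3.5,0.516,20
Shirineshahvar,0.1,0.75,ES,53.12,4.787,20
Shirineshahvar,0.1,0.75,SL,1.69,0.036,20
Shirineshahvar,0.25,0,LN,16.69,1.138,20
Shirineshahvar,0.25,0,PR,3.44,0.512,20
Shirineshahvar,0.25,0,ES,49.37,6.801,20
Shirineshahvar,0.25,0,SL,1.52,0.055,20
Shirineshahvar,0.25,0.25,LN,17.94,0.772,20
Shirineshahvar,0.25,0.25,PR,3.44,0.512,20
Shirineshahvar,0.25,0.25,ES,53.75,6.191,20
Shirineshahvar,0.25,0.25,SL,1.71,0.058,20
Shirineshahvar,0.25,0.5,LN,18.19,0.655,20
Shirineshahvar,0.25,0.5,PR,3.56,0.512,20
Shirineshahvar,0.25,0.5,ES,55.0,5.164,20
Shirineshahvar,0.25,0.5,SL,1.79,0.075,20
Shirineshahvar,0.25,0.75,LN,18.87,0.806,20
Shirineshahvar,0.25,0.75,PR,3.56,0.512,20
Shirineshahvar,0.25,0.75,ES,55.0,5.164,20
Shirineshahvar,0.25,0.75,SL,1.9,0.049,20
Shirineshahvar,0.5,0,LN,17.44,1.093,20
Shirineshahvar,0.5,0,PR,3.37,0.5,20
Shirineshahvar,0.5,0,ES,46.87,4.787,20
Shirineshahvar,0.5,0,SL,1.53,0.058,20
Shirineshahvar,0.5,0.25,LN,18.62,0.957,20
Shirineshahvar,0.5,0.25,PR,3.5,0.516,20
Shirineshahvar,0.5,0.25,ES,56.87,7.932,20
Shirineshahvar,0.5,0.25,SL,1.79,0.129,20
Shirineshahvar,0.5,0.5,LN,18.5,1.155,20
Shirineshahvar,0.5,0.5,PR,3.5,0.516,20
Shirineshahvar,0.5,0.5,ES,59.37,6.801,20
Shirineshahvar,0.5,0.5,SL,1.95,0.078,20
Shirineshahvar,0.5,0.75,LN,18.94,0.772,20
Shirineshahvar,0.5,0.75,PR,3.56,0.512,20
Shirineshahvar,0.5,0.75,ES,61.87,7.5,20
Shirineshahvar,0.5,0.75,SL,1.91,0.093,20
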