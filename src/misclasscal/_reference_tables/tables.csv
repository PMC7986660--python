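table,n,clustering,method,coef,bias,coverage
1,200,gmm,true,beta1,-0.01,0.94
1,200,gmm,true,beta2,0.03,0.94
1,200,gmm,naive,beta1,0.34,0.55
1,200,gmm,naive,beta2,-0.69,0.39
1,200,gmm,simex,beta1,0.07,0.86
1,200,gmm,simex,beta2,-0.17,0.90
1,200,gmm,rc,beta1,0.04,0.85
1,200,gmm,rc,beta2,-0.08,0.90
1,200,kmeans,naive,beta1,0.34,0.60
1,200,kmeans,naive,beta2,-0.67,0.39
1,200,kmeans,simex,beta1,0.07,0.92
1,200,kmeans,simex,beta2,-0.13,0.93
1,200,kmeans,rc,beta1,-0.04,0.94
1,200,kmeans,rc,beta2,0.08,0.94
1,500,gmm,true,beta1,0.00,0.96
1,500,gmm,true,beta2,0.00,0.96
1,500,gmm,naive,beta1,0.36,0.28
1,500,gmm,naive,beta2,-0.71,0.06
1,500,gmm,simex,beta1,0.08,0.88
1,500,gmm,simex,beta2,-0.15,0.91
1,500,gmm,rc,beta1,0.03,0.90
1,500,gmm,rc,beta2,-0.06,0.92
1,500,kmeans,naive,beta1,0.34,0.28
1,500,kmeans,naive,beta2,-0.69,0.05
1,500,kmeans,simex,beta1,0.06,0.92
1,500,kmeans,simex,beta2,-0.14,0.90
1,500,kmeans,rc,beta1,-0.03,0.94
1,500,kmeans,rc,beta2,0.06,0.95
1,1000,gmm,true,beta1,0.00,0.95
1,1000,gmm,true,beta2,0.01,0.96
1,1000,gmm,naive,beta1,0.35,0.08
1,1000,gmm,naive,beta2,-0.69,0.00
1,1000,gmm,simex,beta1,0.06,0.88
1,1000,gmm,simex,beta2,-0.12,0.90
1,1000,gmm,rc,beta1,0.02,0.89
1,1000,gmm,rc,beta2,-0.03,0.93
1,1000,kmeans,naive,beta1,0.35,0.05
1,1000,kmeans,naive,beta2,-0.69,0.00
1,1000,kmeans,simex,beta1,0.08,0.88
1,1000,kmeans,simex,beta2,-0.15,0.88
1,1000,kmeans,rc,beta1,-0.03,0.94
1,1000,kmeans,rc,beta2,0.05,0.94
2,200,gmm,true,beta1,-0.06,0.96
2,200,gmm,true,beta2,0.06,0.95
2,200,gmm,naive,beta1,0.52,0.55
2,200,gmm,naive,beta2,-0.70,0.49
2,200,gmm,simex,beta1,0.14,0.81
2,200,gmm,simex,beta2,-0.17,0.89
2,200,gmm,rc,beta1,0.08,0.80
2,200,gmm,rc,beta2,-0.07,0.90
2,200,kmeans,naive,beta1,1.10,0.02
2,200,kmeans,naive,beta2,-1.16,0.05
2,200,kmeans,simex,beta1,0.83,0.24
2,200,kmeans,simex,beta2,-0.74,0.63
2,200,kmeans,rc,beta1,0.87,0.16
2,200,kmeans,rc,beta2,-0.68,0.67
2,500,gmm,true,beta1,0.00,0.95
2,500,gmm,true,beta2,0.01,0.95
2,500,gmm,naive,beta1,0.57,0.32
2,500,gmm,naive,beta2,-0.75,0.20
2,500,gmm,simex,beta1,0.14,0.82
2,500,gmm,simex,beta2,-0.16,0.89
2,500,gmm,rc,beta1,0.14,0.80
2,500,gmm,rc,beta2,-0.12,0.90
2,500,kmeans,naive,beta1,1.09,0.00
2,500,kmeans,naive,beta2,-1.15,0.00
2,500,kmeans,simex,beta1,0.82,0.04
2,500,kmeans,simex,beta2,-0.73,0.31
2,500,kmeans,rc,beta1,0.86,0.00
2,500,kmeans,rc,beta2,-0.65,0.42
2,1000,gmm,true,beta1,-0.01,0.94
2,1000,gmm,true,beta2,0.01,0.95
2,1000,gmm,naive,beta1,0.53,0.16
2,1000,gmm,naive,beta2,-0.71,0.04
2,1000,gmm,simex,beta1,0.08,0.86
2,1000,gmm,simex,beta2,-0.10,0.89
2,1000,gmm,rc,beta1,0.09,0.82
2,1000,gmm,rc,beta2,-0.08,0.90
2,1000,kmeans,naive,beta1,1.08,0.00
2,1000,kmeans,naive,beta2,-1.15,0.00
2,1000,kmeans,simex,beta1,0.81,0.00
2,1000,kmeans,simex,beta2,-0.72,0.09
2,1000,kmeans,rc,beta1,0.85,0.00
2,1000,kmeans,rc,beta2,-0.65,0.16
3,200,gmm,true,beta2,0.05,0.96
3,200,gmm,naive,beta2,-0.42,0.68
3,200,gmm,simex,beta2,0.16,0.91
3,200,gmm,rc,beta2,-0.01,0.92
3,200,kmeans,naive,beta2,-0.38,0.72
3,200,kmeans,simex,beta2,-0.01,0.92
3,200,kmeans,rc,beta2,0.12,0.94
3,500,gmm,true,beta2,0.02,0.95
3,500,gmm,naive,beta2,-0.42,0.38
3,500,gmm,simex,beta2,-0.07,0.92
3,500,gmm,rc,beta2,-0.02,0.94
3,500,kmeans,naive,beta2,-0.41,0.40
3,500,kmeans,simex,beta2,-0.07,0.91
3,500,kmeans,rc,beta2,0.06,0.94
3,1000,gmm,true,beta2,0.01,0.95
3,1000,gmm,naive,beta2,-0.42,0.11
3,1000,gmm,simex,beta2,-0.07,0.90
3,1000,gmm,rc,beta2,-0.02,0.95
3,1000,kmeans,naive,beta2,-0.42,0.12
3,1000,kmeans,simex,beta2,-0.09,0.89
3,1000,kmeans,rc,beta2,0.04,0.96
4,200,gmm,true,beta2,0.07,0.94
4,200,gmm,naive,beta2,-0.40,0.72
4,200,gmm,simex,beta2,0.03,0.88
4,200,gmm,rc,beta2,0.05,0.92
4,200,kmeans,naive,beta2,-0.62,0.38
4,200,kmeans,simex,beta2,-0.36,0.79
4,200,kmeans,rc,beta2,-0.35,0.84
4,500,gmm,true,beta2,0.01,0.94
4,500,gmm,naive,beta2,-0.43,0.55
4,500,gmm,simex,beta2,-0.05,0.89
4,500,gmm,rc,beta2,-0.04,0.92
4,500,kmeans,naive,beta2,-0.63,0.06
4,500,kmeans,simex,beta2,-0.39,0.63
4,500,kmeans,rc,beta2,-0.37,0.72
4,1000,gmm,true,beta2,0.01,0.95
4,1000,gmm,naive,beta2,-0.42,0.33
4,1000,gmm,simex,beta2,-0.05,0.92
4,1000,gmm,rc,beta2,-0.03,0.93
4,1000,kmeans,naive,beta2,-0.63,0.00
4,1000,kmeans,simex,beta2,-0.40,0.42
4,1000,kmeans,rc,beta2,-0.39,0.51
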