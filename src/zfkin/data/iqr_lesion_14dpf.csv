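group,climb_posture,dive_posture,duration,ibi,speed
pre control,28.7,14.05,0.136,5.04,7.83
pre control,26.16,14.4,0.113,4.06,7.27
pre control,35.74,18.05,0.119,2.53,4.47
pre control,30.01,23.57,0.125,1.26,3.32
pre control,30.92,18.92,0.175,3.28,6.19
pre control,29.46,15.84,0.194,3.83,7.89
pre control,6.29,9.94,0.169,1.38,4.81
pre control,15.57,7.98,0.131,3.11,5.13
pre control,20.51,13.12,0.138,4.17,7.72
pre control,20.14,15.36,0.169,3.26,6.63
pre lesion,24.18,13.16,0.131,6.2,5.15
pre lesion,19.37,18.62,0.138,2.32,7.81
pre lesion,33.27,18.72,0.122,3.3,5.9
pre lesion,21.64,14.69,0.128,2.6,5.18
pre lesion,32.5,16.35,0.169,3.91,6.48
pre lesion,28.2,17.16,0.169,1.68,6.59
pre lesion,10.11,6.42,0.15,3.91,4.4
pre lesion,23.29,17.03,0.1,2.95,5.89
pre lesion,30.73,10.1,0.15,3.95,8.29
pre lesion,22.8,14.67,0.156,4.61,8.1
post control,26.02,13.49,0.119,4.14,7.82
post control,24.71,14.18,0.1,5.5,7.34
post control,32.91,16.37,0.125,5.63,5.88
post control,26.24,21.08,0.1,1.75,3.42
post control,26.15,18.88,0.119,3.98,5.59
post control,34.05,17.22,0.131,5.06,5.75
post control,4.98,9.41,0.1,1.74,4.02
post control,10.19,15.13,0.088,5.12,4.07
post control,24.15,12.57,0.144,4.92,7.42
post control,27.81,18.68,0.144,3.74,6.66
post lesion,21.22,13.02,0.106,6.42,4.59
post lesion,18.43,11.33,0.106,3.13,7.07
post lesion,26.9,16.54,0.119,3.9,5.56
post lesion,25.77,20.22,0.094,3.41,4.43
post lesion,28.24,16.45,0.113,5.15,5.89
post lesion,38.16,16.41,0.106,3.38,4.17
post lesion,11.72,7.7,0.091,3.29,3.68
post lesion,14.28,8.12,0.119,2.83,4.83
post lesion,27.58,11.96,0.125,4.27,5.83
post lesion,24.03,16.41,0.113,5.1,7.13
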