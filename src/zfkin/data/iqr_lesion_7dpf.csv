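group,climb_posture,dive_posture,duration,ibi,speed
pre control,24.53,14.18,0.113,3.67,9.85
pre control,29.07,16.59,0.088,5.22,6.61
pre control,23.45,16.59,0.094,6.22,7.99
pre control,25.97,15.89,0.125,3.73,9.84
pre control,20.95,15.6,0.094,3.48,6.82
pre control,19.82,19.78,0.1,3.29,9.77
pre control,23.7,13.59,0.119,5.99,7.03
pre control,24.08,18.19,0.095,3.87,8.89
pre control,26.89,12.68,0.088,2.7,6.42
pre control,22.21,14.27,0.113,5.84,7.13
pre control,21.91,17.16,0.113,2.49,9.02
pre control,24.2,14.05,0.131,7.95,6.71
pre control,20.42,16.63,0.088,2.8,5.97
pre control,18.7,11.07,0.094,3.17,6.1
pre control,26.29,10.92,0.094,2.18,6.52
pre control,23.38,11.81,0.063,1.03,7.63
pre control,18.46,13.09,0.106,1.73,7.54
pre lesion,16.27,19.05,0.098,1.64,7.82
pre lesion,22.59,14.01,0.113,6.83,7.65
pre lesion,27.26,17.13,0.088,3.37,8.68
pre lesion,26.93,20.38,0.119,2.15,8.99
pre lesion,26.21,12.07,0.088,4.38,4.64
pre lesion,28.53,14.25,0.094,3.81,7.55
pre lesion,22.4,14.02,0.106,5.1,7.7
pre lesion,21.12,15.35,0.106,3.7,9.32
pre lesion,24.34,13.21,0.1,2.75,7.15
pre lesion,21.1,15.76,0.094,4.42,7.88
pre lesion,25.81,15.31,0.1,4.41,8.61
pre lesion,30.09,13.9,0.119,5.43,7.73
pre lesion,21.85,12.45,0.106,4.18,7.82
pre lesion,19.56,18.35,0.072,2.1,5.06
pre lesion,20.57,10.43,0.091,2.39,6.44
pre lesion,21.79,15.38,0.075,2.69,6.59
pre lesion,22.69,16.77,0.109,2.09,9.98
post control,22.43,24.44,0.1,2.29,9.6
post control,21.46,16.25,0.106,6.89,4.19
post control,29.27,14.18,0.094,3.72,7.25
post control,22.57,14.49,0.069,3.55,7.13
post control,20.13,16.04,0.1,4.93,6.48
post control,23.73,17.81,0.088,3.65,6.99
post control,25.54,12.29,0.119,4.97,5.39
post control,16.56,14.54,0.088,3.4,10.5
post control,25.93,13.75,0.094,4.08,5.71
post control,24.72,15.81,0.119,6.18,5.81
post control,23.33,10.9,0.094,2.99,4.77
post control,23.03,11.87,0.106,7.14,5.5
post control,20.11,13.99,0.088,3.59,6.06
post control,18.18,18.27,0.091,2.46,5.63
post control,21.23,13.98,0.063,0.85,4.65
post control,20.15,13.44,0.094,1.09,5.63
post control,20.3,13.38,0.063,0.84,5.27
post lesion,18.49,13.28,0.063,5.34,5.32
post lesion,24.95,12.55,0.113,7.19,4.72
post lesion,28.4,15.31,0.078,4.29,7.82
post lesion,27.02,11.85,0.106,6.3,6.02
post lesion,23.87,11.08,0.063,5.39,5.24
post lesion,23.9,12.96,0.069,1.96,6.24
post lesion,26.79,11.18,0.069,0.91,5.87
post lesion,26.27,15.42,0.094,4.43,8.02
post lesion,25.66,14.43,0.1,6.43,5.88
post lesion,24.62,13.05,0.125,6.24,5.66
post lesion,25.76,12.31,0.1,4.98,7.33
post lesion,28.85,12.47,0.094,6.11,5.98
post lesion,22.35,13.41,0.075,1.85,6.94
post lesion,22.36,17.24,0.088,3.17,5.22
post lesion,22.52,14.74,0.069,0.88,5.07
post lesion,27.76,12.45,0.094,2.01,4.49
post lesion,24.21,12.28,0.056,1.16,4.98
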