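group,climb_posture,dive_posture,duration,ibi,speed
pre control,20.74,23.65,0.075,1.33,7.36
pre control,28.21,16.96,0.125,1.0,7.28
pre control,29.9,24.49,0.125,1.4,9.43
pre control,24.84,17.06,0.075,1.55,7.96
pre control,22.6,18.18,0.075,1.6,7.64
pre control,23.63,15.56,0.075,2.04,4.99
pre control,18.86,17.54,0.1,2.48,6.69
pre control,22.52,15.44,0.075,2.03,6.93
pre control,23.0,11.93,0.081,2.38,6.92
pre control,20.05,14.85,0.075,1.61,7.3
pre control,19.29,18.75,0.1,2.3,6.0
pre control,22.25,14.81,0.075,2.23,6.25
pre control,21.61,17.06,0.075,1.95,6.36
pre control,24.16,18.94,0.1,1.68,6.66
pre control,19.63,10.03,0.05,1.75,6.68
pre control,22.35,16.96,0.1,1.9,6.44
pre control,21.22,13.89,0.1,2.5,7.08
pre control,21.61,14.43,0.075,1.68,7.1
pre activation,24.68,16.86,0.081,1.87,7.44
pre activation,25.48,13.85,0.1,1.3,7.71
pre activation,25.88,13.53,0.1,1.08,6.48
pre activation,24.92,16.52,0.075,1.68,7.13
pre activation,20.3,18.64,0.075,1.38,4.41
pre activation,23.32,21.46,0.1,2.99,6.39
pre activation,25.03,15.73,0.1,1.83,6.68
pre activation,21.49,14.53,0.1,2.12,6.38
pre activation,25.84,16.73,0.1,1.58,6.66
pre activation,22.33,12.52,0.075,2.1,6.67
pre activation,20.44,16.83,0.075,3.1,6.05
pre activation,23.67,16.49,0.1,2.78,6.38
pre activation,27.07,19.06,0.1,2.7,6.32
pre activation,23.81,17.4,0.075,1.66,7.31
pre activation,21.82,19.38,0.05,2.33,7.68
pre activation,24.27,16.03,0.1,2.33,6.73
pre activation,23.44,16.06,0.1,1.98,7.12
pre activation,22.89,15.45,0.1,1.58,6.93
control,21.1,16.75,0.05,0.43,5.69
control,24.43,43.2,0.1,1.4,7.61
control,36.4,18.92,0.1,1.56,8.08
control,21.95,18.46,0.075,1.96,7.08
control,21.82,20.37,0.075,1.25,8.0
control,20.74,19.04,0.075,1.98,6.57
control,22.37,20.55,0.075,1.53,6.95
control,21.79,13.07,0.075,2.05,7.4
control,23.97,16.79,0.075,2.43,6.41
control,22.48,16.57,0.075,2.09,6.38
control,21.13,21.03,0.075,2.33,6.43
control,23.19,17.84,0.075,1.98,6.47
control,22.4,18.91,0.075,1.73,6.46
control,25.41,20.43,0.075,2.08,6.83
control,29.93,18.46,0.075,1.9,5.79
control,24.37,25.53,0.1,1.8,6.58
control,26.21,19.68,0.1,1.53,6.1
control,20.5,18.0,0.075,1.5,6.32
activation,23.4,28.68,0.075,0.65,6.53
activation,26.09,11.16,0.075,1.65,7.51
activation,21.35,19.42,0.05,0.75,6.68
activation,23.69,13.84,0.075,2.31,6.34
activation,19.9,15.18,0.05,1.25,5.33
activation,24.64,20.85,0.05,1.96,6.96
activation,23.64,22.08,0.075,1.78,7.22
activation,21.78,18.14,0.1,2.19,6.98
activation,24.24,17.35,0.1,2.57,8.79
activation,27.93,13.88,0.1,2.63,7.56
activation,23.48,21.2,0.075,2.51,6.25
activation,26.16,20.58,0.1,2.33,6.95
activation,27.49,26.34,0.081,1.73,6.6
activation,26.88,23.4,0.075,1.85,7.78
activation,25.26,19.62,0.075,2.1,7.6
activation,24.41,20.94,0.1,2.33,6.47
activation,26.64,19.76,0.1,1.9,6.69
activation,23.86,19.33,0.075,1.53,6.45
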