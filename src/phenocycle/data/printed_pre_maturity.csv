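treatment,trait,parent,parent_mean,parent_sd,nil,nil_mean,nil_sd,printed_p,printed_sig
control,TN DAS28,BarNir,3.00,0.67,NIL-B-7A-2,2.90,1.10,0.81,0
control,TN DAS28,Zahir,2.30,0.48,NIL-Z-7A-5,2.10,0.57,0.41,0
control,TN DAS28,Uzan,2.90,0.32,NIL-U-2B-3,2.90,0.74,1.00,0
control,TN DAS53,BarNir,6.30,1.25,NIL-B-7A-2,5.90,1.60,0.54,0
control,TN DAS53,Zahir,3.40,0.52,NIL-Z-7A-5,3.00,0.47,0.09,0
control,TN DAS53,Uzan,3.70,1.06,NIL-U-2B-3,4.50,1.27,0.14,0
control,TN DAS70,BarNir,6.60,1.07,NIL-B-7A-2,7.10,1.60,0.42,0
control,TN DAS70,Zahir,3.80,0.79,NIL-Z-7A-5,3.80,0.63,1.00,0
control,TN DAS70,Uzan,5.70,0.95,NIL-U-2B-3,7.40,2.32,0.05,1
control,Gain of TN DAS28 and 53,BarNir,3.30,1.06,NIL-B-7A-2,3.00,1.05,0.53,0
control,Gain of TN DAS28 and 53,Zahir,1.10,0.57,NIL-Z-7A-5,0.90,0.57,0.44,0
control,Gain of TN DAS28 and 53,Uzan,0.80,1.14,NIL-U-2B-3,1.60,1.26,0.15,0
control,Gain of TN DAS53 and 70,BarNir,0.30,0.48,NIL-B-7A-2,1.20,0.79,0.01,1
control,Gain of TN DAS53 and 70,Zahir,0.40,0.70,NIL-Z-7A-5,0.80,0.63,0.20,0
control,Gain of TN DAS53 and 70,Uzan,2.00,1.49,NIL-U-2B-3,2.90,2.42,0.33,0
control,Gain of TN DAS28 and 70,BarNir,3.60,0.97,NIL-B-7A-2,4.20,1.03,0.20,0
control,Gain of TN DAS28 and 70,Zahir,1.50,0.85,NIL-Z-7A-5,1.70,0.67,0.57,0
control,Gain of TN DAS28 and 70,Uzan,2.80,0.92,NIL-U-2B-3,4.50,1.84,0.02,1
control,BBCH55 in DAS,BarNir,46.60,0.97,NIL-B-7A-2,47.00,1.49,0.49,0
control,BBCH55 in DAS,Zahir,55.60,2.99,NIL-Z-7A-5,54.00,2.87,0.24,0
control,BBCH55 in DAS,Uzan,50.00,0.67,NIL-U-2B-3,49.80,1.40,0.69,0
control,Flag Leaf Width (mm),BarNir,14.50,0.53,NIL-B-7A-2,15.80,1.75,0.04,1
control,Flag Leaf Width (mm),Zahir,18.20,1.14,NIL-Z-7A-5,18.00,0.82,0.66,0
control,Flag Leaf Width (mm),Uzan,18.00,1.15,NIL-U-2B-3,18.10,1.66,0.88,0
control,Flag Leaf Length (cm),BarNir,32.28,1.40,NIL-B-7A-2,33.89,3.40,0.18,0
control,Flag Leaf Length (cm),Zahir,24.76,2.53,NIL-Z-7A-5,25.60,2.17,0.44,0
control,Flag Leaf Length (cm),Uzan,26.45,1.94,NIL-U-2B-3,25.40,1.39,0.18,0
control,Flag Leaf Area (cm2),BarNir,156.53,6.12,NIL-B-7A-2,188.03,26.44,0.00,1
control,Flag Leaf Area (cm2),Zahir,244.13,20.29,NIL-Z-7A-5,242.93,14.08,0.88,0
control,Flag Leaf Area (cm2),Uzan,239.93,21.03,NIL-U-2B-3,241.88,31.82,0.87,0
control,Osmotic Potential (MPa),BarNir,-1.53,0.08,NIL-B-7A-2,-1.52,0.09,0.76,0
control,Osmotic Potential (MPa),Zahir,-1.34,0.13,NIL-Z-7A-5,-1.38,0.13,0.45,0
control,Osmotic Potential (MPa),Uzan,-1.54,0.14,NIL-U-2B-3,-1.58,0.13,0.57,0
control,QY-H DAS 69,BarNir,0.44,0.01,NIL-B-7A-2,0.47,0.01,0.00,1
control,QY-H DAS 69,Zahir,0.46,0.01,NIL-Z-7A-5,0.47,0.01,0.50,0
control,QY-H DAS 69,Uzan,0.47,0.01,NIL-U-2B-3,0.47,0.01,0.86,0
control,QY-H DAS 74,BarNir,0.44,0.01,NIL-B-7A-2,0.46,0.02,0.09,0
control,QY-H DAS 74,Zahir,0.46,0.01,NIL-Z-7A-5,0.46,0.01,0.74,0
control,QY-H DAS 74,Uzan,0.46,0.01,NIL-U-2B-3,0.46,0.01,1.00,0
control,QY-L DAS 69,BarNir,0.51,0.01,NIL-B-7A-2,0.51,0.01,0.57,0
control,QY-L DAS 69,Zahir,0.51,0.01,NIL-Z-7A-5,0.51,0.01,0.18,0
control,QY-L DAS 69,Uzan,0.53,0.02,NIL-U-2B-3,0.53,0.01,0.66,0
control,QY-L DAS 74,BarNir,0.52,0.01,NIL-B-7A-2,0.53,0.02,0.04,1
control,QY-L DAS 74,Zahir,0.51,0.02,NIL-Z-7A-5,0.51,0.01,0.88,0
control,QY-L DAS 74,Uzan,0.52,0.02,NIL-U-2B-3,0.53,0.01,0.16,0
control,QY-LH Ratio DAS 69,BarNir,1.15,0.03,NIL-B-7A-2,1.09,0.02,0.00,1
control,QY-LH Ratio DAS 69,Zahir,1.09,0.04,NIL-Z-7A-5,1.10,0.03,0.70,0
control,QY-LH Ratio DAS 69,Uzan,1.12,0.04,NIL-U-2B-3,1.12,0.02,0.75,0
control,QY-LH Ratio DAS 74,BarNir,1.17,0.03,NIL-B-7A-2,1.16,0.03,0.98,0
control,QY-LH Ratio DAS 74,Zahir,1.12,0.04,NIL-Z-7A-5,1.12,0.04,0.90,0
control,QY-LH Ratio DAS 74,Uzan,1.13,0.04,NIL-U-2B-3,1.15,0.03,0.18,0
stress,TN DAS28,BarNir,2.60,0.52,NIL-B-7A-2,2.80,0.42,0.36,0
stress,TN DAS28,Zahir,2.20,0.79,NIL-Z-7A-5,2.00,0.67,0.55,0
stress,TN DAS28,Uzan,2.40,0.52,NIL-U-2B-3,3.30,0.48,0.00,1
stress,TN DAS53,BarNir,4.10,0.99,NIL-B-7A-2,4.40,1.07,0.53,0
stress,TN DAS53,Zahir,2.70,0.48,NIL-Z-7A-5,2.80,0.63,0.70,0
stress,TN DAS53,Uzan,3.00,0.47,NIL-U-2B-3,3.80,0.42,0.00,1
stress,TN DAS70,BarNir,4.40,0.97,NIL-B-7A-2,4.60,1.26,0.70,0
stress,TN DAS70,Zahir,3.00,0.67,NIL-Z-7A-5,3.00,0.47,1.00,0
stress,TN DAS70,Uzan,3.30,0.48,NIL-U-2B-3,5.10,0.88,0.00,1
stress,Gain of TN DAS28 and 53,BarNir,1.50,0.97,NIL-B-7A-2,1.60,0.97,0.82,0
stress,Gain of TN DAS28 and 53,Zahir,0.50,0.53,NIL-Z-7A-5,0.80,0.92,0.38,0
stress,Gain of TN DAS28 and 53,Uzan,0.60,0.70,NIL-U-2B-3,0.50,0.53,0.72,0
stress,Gain of TN DAS53 and 70,BarNir,0.30,0.48,NIL-B-7A-2,0.20,1.03,0.78,0
stress,Gain of TN DAS53 and 70,Zahir,0.30,0.67,NIL-Z-7A-5,0.20,0.42,0.70,0
stress,Gain of TN DAS53 and 70,Uzan,0.30,0.82,NIL-U-2B-3,1.30,1.06,0.03,1
stress,Gain of TN DAS28 and 70,BarNir,1.80,0.92,NIL-B-7A-2,1.80,1.32,1.00,0
stress,Gain of TN DAS28 and 70,Zahir,0.80,0.79,NIL-Z-7A-5,1.00,082,0.58,0
stress,Gain of TN DAS28 and 70,Uzan,0.90,0.74,NIL-U-2B-3,1.80,1.03,0.04,1
stress,BBCH55 in DAS,BarNir,45.20,0.63,NIL-B-7A-2,46.20,0.92,0.01,1
stress,BBCH55 in DAS,Zahir,52.60,1.84,NIL-Z-7A-5,52.80,2.39,0.84,0
stress,BBCH55 in DAS,Uzan,48.30,0.67,NIL-U-2B-3,47.50,1.27,0.10,0
stress,Flag Leaf Width (mm),BarNir,15.00,1.15,NIL-B-7A-2,15.70,1.16,0.19,0
stress,Flag Leaf Width (mm),Zahir,16.50,1.72,NIL-Z-7A-5,15.90,1.37,0.40,0
stress,Flag Leaf Width (mm),Uzan,16.60,0.97,NIL-U-2B-3,16.40,2.07,0.78,0
stress,Flag Leaf Length (cm),BarNir,31.46,1.05,NIL-B-7A-2,35.78,1.81,0.00,1
stress,Flag Leaf Length (cm),Zahir,16.28,3.43,NIL-Z-7A-5,17.55,5.30,0.53,0
stress,Flag Leaf Length (cm),Uzan,23.28,0.67,NIL-U-2B-3,22.96,3.21,0.76,0
stress,Flag Leaf Area (cm2),BarNir,168.53,15.57,NIL-B-7A-2,189.98,26.62,0.04,1
stress,Flag Leaf Area (cm2),Zahir,204.60,22.68,NIL-Z-7A-5,189.83,25.46,0.19,0
stress,Flag Leaf Area (cm2),Uzan,213.08,22.28,NIL-U-2B-3,182.66,72.86,0.22,0
stress,Osmotic Potential (MPa),BarNir,-1.86,0.14,NIL-B-7A-2,-1.89,0.11,0.52,0
stress,Osmotic Potential (MPa),Zahir,-1.73,0.22,NIL-Z-7A-5,-1.72,0.18,0.93,0
stress,Osmotic Potential (MPa),Uzan,-1.82,0.07,NIL-U-2B-3,-1.89,0.12,0.15,0
stress,QY-H DAS 69,BarNir,0.42,0.02,NIL-B-7A-2,0.46,0.01,0.00,1
stress,QY-H DAS 69,Zahir,0.45,0.02,NIL-Z-7A-5,0.44,0.02,0.57,0
stress,QY-H DAS 69,Uzan,0.44,0.02,NIL-U-2B-3,0.43,0.02,0.11,0
stress,QY-H DAS 74,BarNir,0.41,0.01,NIL-B-7A-2,0.45,0.01,0.00,1
stress,QY-H DAS 74,Zahir,0.44,0.01,NIL-Z-7A-5,0.44,0.01,0.82,0
stress,QY-H DAS 74,Uzan,0.42,0.02,NIL-U-2B-3,0.39,0.07,0.14,0
stress,QY-L DAS 69,BarNir,0.49,0.02,NIL-B-7A-2,0.51,0.02,0.16,0
stress,QY-L DAS 69,Zahir,0.50,0.02,NIL-Z-7A-5,0.50,0.01,0.45,0
stress,QY-L DAS 69,Uzan,0.51,0.02,NIL-U-2B-3,0.49,0.01,0.18,0
stress,QY-L DAS 74,BarNir,0.49,0.03,NIL-B-7A-2,0.51,0.02,0.18,0
stress,QY-L DAS 74,Zahir,0.50,0.02,NIL-Z-7A-5,0.50,0.02,0.85,0
stress,QY-L DAS 74,Uzan,0.48,0.03,NIL-U-2B-3,0.47,0.01,0.17,0
stress,QY-LH Ratio DAS 69,BarNir,1.18,0.03,NIL-B-7A-2,1.12,0.04,0.00,1
stress,QY-LH Ratio DAS 69,Zahir,1.11,0.03,NIL-Z-7A-5,1.14,0.05,0.20,0
stress,QY-LH Ratio DAS 69,Uzan,1.14,0.04,NIL-U-2B-3,1.16,0.05,0.43,0
stress,QY-LH Ratio DAS 74,BarNir,1.20,0.06,NIL-B-7A-2,1.14,0.05,0.02,1
stress,QY-LH Ratio DAS 74,Zahir,1.14,0.05,NIL-Z-7A-5,1.15,0.04,0.72,0
stress,QY-LH Ratio DAS 74,Uzan,1.15,0.04,NIL-U-2B-3,1.29,0.43,0.31,0
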