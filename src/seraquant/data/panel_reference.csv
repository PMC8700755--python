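analyte,name,units,range_low,range_high,test_true,test_found,delta_pct
B1,Uric acid,umol/L,58.40,292.00,131.00,130.96,0.03
B2,Total bilirubin,umol/L,5.78,28.90,17.58,17.57,0.06
B3,Direct bilirubin,umol/L,3.06,15.30,7.90,7.89,0.08
B4,Creatinine,umol/L,18.02,90.10,59.00,58.95,0.08
B5,Fructosamine,umol/L,147.40,737.00,193.80,193.68,0.06
B6,Glucose,mmol/L,1.04,5.22,2.76,2.76,0.07
B7,Lactate,mmol/L,0.30,1.52,0.70,0.70,0.07
B8,Urea,mmol/L,1.39,6.97,4.20,4.20,0.06
B9,Cholesterol,mmol/L,0.48,2.39,1.00,1.00,0.07
B10,HDL-Cholesterol,mmol/L,0.14,0.72,0.36,0.36,0.06
B11,LDL-Cholesterol,mmol/L,0.27,1.34,0.36,0.36,0.07
B12,Phospholipids,mmol/L,0.32,1.60,0.57,0.57,0.08
B13,Triglycerides,mmol/L,0.25,1.24,0.47,0.47,0.08
B14,Calcium,mmol/L,0.44,2.22,0.70,0.70,0.07
B15,Chlorides,mmol/L,16.20,81.00,21.60,21.58,0.10
B16,Copper,umol/L,3.64,18.20,6.60,6.60,0.06
B17,Iron,umol/L,3.68,18.40,8.48,8.47,0.08
B18,Total Iron binding capacity,umol/L,13.74,68.70,13.74,13.73,0.10
B19,Potassium,mmol/L,0.70,3.51,4.78,4.78,0.09
B20,Lithium,mmol/L,0.20,1.00,0.49,0.49,0.07
B21,Magnesium,mmol/L,0.17,0.87,0.27,0.27,0.06
B22,Sodium,mmol/L,25.20,126.00,29.20,29.18,0.09
B23,Phosphorus,mmol/L,0.27,1.36,0.47,0.47,0.08
B24,Zinc,ug/mL,77.40,387.00,68.40,68.35,0.08
B25,Total Protein,g/L,13.24,66.20,10.10,10.09,0.07
B26,Albumin,g/L,9.78,48.90,6.92,6.91,0.08
B27,alpha-amylase,U/L,16.40,82.00,40.80,40.77,0.08
B28,Creatinekinase,U/L,29.00,145.00,98.80,98.73,0.07
B29,Cholinesterase,U/L,1107.80,5539.00,1100.20,1099.39,0.07
B30,Acid Phosphatase,U/L,6.72,33.60,11.38,11.37,0.07
B31,Alkaline Phosphatase,U/L,15.20,76.00,42.40,42.37,0.06
B32,Gamma glutamyltransferase,U/L,8.40,42.00,39.80,39.77,0.09
B33,Asparagine aminotransferase,U/L,10.60,53.00,31.80,31.77,0.09
B34,Alanine aminotransferase,U/L,10.40,52.00,28.40,28.38,0.08
B35,Lipase,U/L,7.86,39.30,16.90,16.89,0.07
B36,Lactate dehydrogenase,U/L,78.00,390.00,148.80,148.70,0.07
B37,Glutamate dehydrogenase,U/L,4.98,24.90,8.42,8.41,0.07
B38,alpha-hydroxybutyrate dehydrogenase,U/L,31.00,155.00,63.00,62.95,0.08
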