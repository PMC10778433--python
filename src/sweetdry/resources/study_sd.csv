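id,phenols,dpph,abts,rp,soa,aia,ahga,L,a,b,moisture,proteins,fats,sugars,cellulose,ash,carbs,K,Mg,Ca,Fe,Na
1,9.80,25.52,26.23,29.08,273.52,0.2,0.26,0.06,0.03,0.24,0.57,0.63,0.11,3.43,0.97,0.37,,13.65,45.35,350.2,1.56,59.31
2,16.17,30.45,32.48,29.03,290.41,1.29,1.39,0.15,0.11,0.13,0.67,0.67,0.09,6.01,0.67,0.36,,2123.32,110.45,240.8,3.15,5.36
3,17.35,23.32,3.75,17.21,386.25,1.83,0.21,0.31,0.02,0.14,0.78,0.65,0.08,4.35,0.89,0.67,,2708.2,109.91,210.7,7.24,1186.6
4,10.12,22.67,3.12,3.18,281.68,1.56,0.04,0.09,0.01,0.05,0.35,0.71,0.09,3.73,0.97,0.2,,2520.42,157.21,349.4,1.92,65.91
5,5.63,27.58,68.48,2.92,524.17,1.9,0.76,0.06,0.02,0.11,0.51,0.74,0.1,4.62,1.0,0.37,,2293.52,113.01,204.4,2.79,103.2
6,7.16,17.21,43.77,24.16,120.91,1.46,0.17,0.11,0.03,0.09,1.01,0.69,0.08,4.42,0.81,0.6,,3019.87,106.35,180.2,8.09,1048.02
7,27.89,6.15,65.54,17.00,543.81,1.13,0.13,0.06,0.22,0.30,0.38,0.58,0.12,3.61,0.75,0.33,,2602.54,101.13,124.7,1.68,35.22
8,11.78,23.16,6.25,12.75,249.45,0.45,3.08,0.08,0.15,0.29,0.43,0.62,0.13,4.27,0.9,0.36,,2558.16,109.32,183.6,2.41,82.72
9,17.13,16.19,39.98,4.54,431.31,0.91,0.48,0.10,0.11,0.13,0.88,0.54,0.14,4.87,0.94,0.55,,2342.53,94.33,142.5,2.43,1195.94
10,61.23,35.63,8.59,51.33,50.17,0.94,0.50,0.33,0.21,0.01,0.33,0.65,0.09,2.38,0.85,0.26,,1189.97,82.3,237.88,1.37,49.16
11,82.94,31.09,89.21,31.17,42.18,0.68,1.11,0.15,0.08,0.06,0.25,0.55,0.08,2.85,0.93,0.28,,1545.87,58.84,175.29,1.31,49.12
12,113.7,33.52,103.69,78.41,52.56,0.89,1.44,0.19,0.08,0.04,0.19,0.45,0.07,2.79,0.82,0.44,,10771.55,81.55,128.6,5.08,700.02
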