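id,variety,method,phenols,dpph,abts,rp,soa,aia,ahga,L,a,b,moisture,proteins,fats,sugars,cellulose,ash,carbs,K,Mg,Ca,Fe,Na
1,white,lyophilization,191.44,454.92,988.46,549.22,18793.31,5.56,8.06,86.32,-0.95,16.99,5.12,12.32,0.72,25.47,4.53,4.92,77.85,26140.70,1009.14,3179.92,24.6,415.92
2,white,convective,278.24,687.53,586.54,1324.76,21305.91,49.40,61.56,80.65,1.33,18.72,6.03,13.07,0.57,45.14,5.47,4.73,76.71,25111.59,1358.6,2211.47,33.41,52.96
3,white,osmotic,283.06,619.05,1855.91,570.92,18651.15,54.07,3.37,65.36,5.36,23.17,7.1,12.49,0.55,32.94,4.15,8.89,72.52,28673.71,964.91,2665.09,72.91,14272.88
4,pink,lyophilization,182.75,297.73,890.41,451.67,21135.65,50.62,1.49,85.75,-0.04,14.69,3.2,13.8,0.61,27.18,4.55,2.63,80.31,27530.03,1660.47,3565.12,26.32,560.74
5,pink,convective,207.45,451.63,1756.68,1025.29,18221.36,56.81,40.10,85.75,0.83,17.74,4.61,14.27,0.68,34.13,4.7,4.84,76.51,26148.12,1116.89,1975.157,24.61,869.513
6,pink,osmotic,255.29,500.41,1720.31,569.95,13714.78,56.39,4.18,63.38,6.33,25.02,9.05,13.4,0.57,34.42,3.78,8.00,70.92,30571.70,880.21,1818.41,71.95,13368.26
7,orange,lyophilization,376.64,680.66,2025.80,977.26,21367.07,45.40,6.51,79.13,17.66,22.74,3.48,11.2,0.75,26.39,3.5,4.36,80.77,28030.08,846.53,1458.31,17.37,425.71
8,orange,convective,211.55,449.92,1857.67,786.29,17619.65,45.84,44.40,80.79,7.32,28.88,3.88,12.04,0.83,31.36,4.22,4.76,79.17,27759.82,899.41,1840.84,35.06,605.2
9,orange,osmotic,227.53,381.78,1584.72,568.98,8778.42,58.72,4.99,64.50,18.04,27.21,7.93,10.5,0.92,37.28,4.39,7.24,74.89,26446.61,996.28,1249.4,35.23,11070.1
10,purple,lyophilization,1677.76,1500.56,10083.37,3130.81,22753.97,8.93,24.42,57.97,21.09,-9.36,2.97,12.6,0.60,17.29,3.97,3.45,80.89,19427.35,1241.44,2841.53,21.86,516.69
11,purple,convective,1428.23,1253.21,7547.88,2595.32,22529.16,20.14,23.04,55.74,16.61,-0.01,2.27,10.75,0.54,20.6,4.33,3.74,83.04,21594.92,1025.13,1786.42,15.01,516.44
12,purple,osmotic,2006.81,1172.29,5316.85,2544.64,22580.40,5.94,13.32,55.26,15.78,-4.67,5.53,10.62,0.42,20.47,3.85,5.87,80.05,14392.76,720.05,1483.48,58.9,6919.21
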