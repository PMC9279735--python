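study,sib_doses,initial_dmean,final_dmean,delta_dmean,laterality,de0,fraction_de0,cumdose_de0,fraction_de10,cumdose_de10
46,70/63/56,19.66,22.25,2.60,Left,20,2,4,22,44
81,70/63/56,19.54,25.85,6.31,Left,20,1,2,1,2
79,70/63/56,19.98,23.17,3.19,Left,20,1,2,1,2
137,70/63/56,19.63,24.00,4.37,Left,20,2,4,4,8
94,66/60/54,19.40,20.95,1.55,Right,20,12,24,20,40
105,66/54,19.24,20.23,0.99,Right,20,21,42,,
22,70/63/56,19.56,20.87,1.20,Right,20,30,60,,
26,70/63/56,19.91,20.11,2.29,Right,20,16,32,,
78,60/54,19.57,21.86,2.29,Left,20,9,18,,
116,60/54,17.62,20.29,2.68,Right,20,16,32,,
83,70/63/56,19.74,25.44,5.70,Left,20,2,4,2,4
118,70/63/56,20.76,25.72,4.97,Left,21,2,4,9,18
137,70/63/56,20.21,23.77,3.56,Right,21,2,4,5,10
146,70/63/56,20.42,22.37,1.95,Right,21,1,2,,
81,70/63/56,25.66,29.14,3.48,Right,26,5,10,23,46
79,70/63/56,25.24,26.93,1.69,Right,26,12,24,,
105,59.4/54.12,25.47,27.82,2.35,Left,26,1,2,,
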