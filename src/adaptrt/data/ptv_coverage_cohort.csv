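study,target,initial_v95,final_v95,delta_v95,fraction_warning,cumulative_dose_gy
94,IR PTV60 GTV+nodes,100.00,93.74,-6.26,10,20
118,IR PTV63 GTV+nodes,99.43,92.86,-6.57,16,32
146,IR PTV63 GTV+nodes,99.43,93.55,-5.88,1,2
46,IR PTV63 GTV+nodes,99.27,94.76,-4.51,35,70
15,PTV60,98.98,90.03,-8.95,3,6
8,PTV60 Post-op bed,98.12,84.45,-13.67,9,18
8,PTV54 Nodal basin,98.36,92.17,-6.19,13,26
99,PTV60 Post-op bed,94.67,93.27,-1.40,1,2
19,IR PTV63 GTV+nodes,99.38,94.21,-5.17,31,62
19,LR PTV56 GTV+nodes,96.29,89.15,-7.14,2,4
18,IR PTV63 GTV+nodes,99.50,89.56,-9.94,1,2
18,LR PTV56 GTV+nodes,99.97,93.81,-6.16,3,6
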