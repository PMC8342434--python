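T_K,P_bar,y,rho_gL,S_gL
303.15,90,2.18e-5,681.6,0.09674
303.15,115,2.92e-5,758.1,0.1441
303.15,130,3.58e-5,789,0.1839
303.15,140,4.12e-5,806.5,0.2162
303.15,155,5.29e-5,829.3,0.2855
303.15,175,6.01e-5,855.3,0.3345
303.15,185,6.25e-5,866.9,0.3527
303.15,195,7.21e-5,877.7,0.4118
303.15,220,7.96e-5,901.9,0.4672
303.15,230,8.19e-5,910.7,0.4854
303.15,245,8.32e-5,923,0.4998
313.15,100,1.68e-5,561.3,0.06136
313.15,120,3.62e-5,664.1,0.1565
313.15,130,5.41e-5,696.5,0.2453
313.15,140,5.25e-5,723.2,0.2471
313.15,155,6.63e-5,756.3,0.3263
313.15,170,8.13e-5,783.8,0.4148
313.15,200,1.255e-4,828.3,0.6766
313.15,235,1.38e-4,869.1,0.7808
313.15,245,1.492e-4,879.2,0.8540
323.15,110,2.68e-5,462.2,0.08062
323.15,135,5.24e-5,603,0.2056
323.15,165,1.014e-4,693,0.4575
323.15,180,1.402e-4,725.3,0.6619
323.15,195,1.482e-4,752.6,0.7260
323.15,205,1.6e-4,768.9,0.8008
323.15,235,1.964e-4,810.5,1.036
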