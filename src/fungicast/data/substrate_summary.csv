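label,bs_pct,hs_pct,wb_pct,rb_pct,cn_ratio,n,srp_mean,srp_se,dphf_mean,dphf_se,dffh_mean,dffh_se,nfb_mean,nfb_se,yield_mean,yield_se,be_mean,be_se,tcp_mean,tcp_se
HS(100),0,100,0,0,111.9,12,41.5,0.65,46.2,0.85,51.5,0.65,5.9,0.65,68.7,0.25,27.9,0.25,60.5,0.90
BS(100),100,0,0,0,106.4,12,37.7,0.48,42.5,0.65,49.5,0.65,5.5,0.55,71.7,0.65,29.1,0.65,60.5,0.93
HS(90)+RB(10),0,90,0,10,77.0,12,31.7,0.48,36.7,0.48,41.5,0.65,6.3,0.65,87.7,0.85,35.5,0.85,53.5,0.53
BS(90)+RB(10),90,0,0,10,76.4,12,27.7,0.48,33.7,0.48,39.5,0.65,7.1,0.80,90.7,0.85,36.7,0.85,51.5,0.93
HS(90)+WB(10),0,90,10,0,111.3,12,25.7,0.17,34.0,0.41,38.5,0.65,7.2,0.45,88.7,0.85,35.9,0.85,50.5,0.46
BS(90)+WB(10),90,0,10,0,78.4,12,25.7,0.48,32.2,0.48,37.5,0.65,7.5,0.66,99.7,0.90,40.3,0.90,49.0,0.90
HS(80)+RB(20),0,80,0,20,58.2,12,29.7,0.48,35.7,0.85,40.5,0.65,7.4,0.65,111.7,0.85,45.1,0.85,52.5,0.33
BS(80)+RB(20),80,0,0,20,58.3,12,23.7,0.48,29.2,1.31,38.5,0.65,7.6,0.65,114.7,0.85,46.3,0.85,50.5,0.99
HS(80)+WB(20),0,80,20,0,60.5,12,24.7,0.48,31.2,1.31,38.5,0.65,7.8,0.09,114.7,0.05,46.3,0.05,50.5,0.75
BS(80)+WB(20),80,0,20,0,60.5,12,21.7,0.09,28.5,1.55,35.5,0.65,8.2,0.60,117.7,0.16,47.5,0.16,45.5,0.43
HS(70)+RB(30),0,70,0,30,46.9,12,27.7,0.21,34.0,2.04,38.5,0.65,8.2,0.65,116.7,0.80,47.1,0.80,51.5,0.93
BS(70)+RB(30),70,0,0,30,47.2,12,21.7,0.08,29.7,1.80,33.5,0.65,8.6,0.71,122.7,0.55,49.5,0.55,46.5,0.93
HS(70)+WB(30),0,70,30,0,49.1,12,23.7,0.48,31.0,2.29,34.5,0.65,8.7,0.65,120.7,0.85,48.7,0.85,47.5,0.88
BS(70)+WB(30),70,0,30,0,49.2,12,19.7,0.28,27.5,2.53,30.5,0.65,9.0,0.65,131.7,0.85,53.1,0.85,43.5,0.93
WB(100),0,0,100,0,18.0,12,37.7,0.38,47.2,2.29,50.5,0.65,4.5,0.10,56.7,0.15,23.1,0.15,60.5,0.93
RB(100),0,0,0,100,17.7,12,34.7,0.48,43.7,2.78,47.5,0.65,4.8,0.62,61.7,0.66,25.1,0.66,59.5,0.33
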