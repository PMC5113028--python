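tool,mode,ay_ms2,axz_ms2,at_ms2,provenance,identity_ok
Vibrating fork,unweighted,10.35,23.02,25.24,Table 3,True
Vibrating fork,weighted,5.68,10.74,12.15,Table 3,True
Pavement tamper,unweighted,14.25,29.68,33.2,Table 3,False
Pavement tamper,weighted,10.17,12.67,18.19,Table 3,False
Chipping hammer,unweighted,27.68,67.86,73.3,Table 3,False
Chipping hammer,weighted,2.7,11.84,12.16,Table 3,False
Rivet hammer,unweighted,92.25,143.34,170.46,Table 3,True
Rivet hammer,weighted,7.71,18.92,20.44,Table 3,True
Impact wrench,unweighted,36.53,86.26,93.68,Table 3,True
Impact wrench,weighted,3.23,5.73,6.58,Table 3,True
Vertical grinder,unweighted,154.84,136.14,206.18,Table 3,True
Vertical grinder,weighted,6.3,9.41,11.33,Table 3,True
Pavement cutting saw,unweighted,46.1,94.97,105.58,Table 3,False
Pavement cutting saw,weighted,5.3,10.9,12.12,Table 3,True
Sander,unweighted,11.59,94.63,95.34,Table 3,True
Sander,weighted,0.81,9.87,9.9,Table 3,True
Stone hammer - chisel,unweighted,217.55,120.82,248.84,Table 5,True
Stone hammer - chisel,weighted,17.35,8.46,19.31,Table 5,True
Stone hammer - handle,unweighted,60.01,173.69,183.77,Table 5,True
Stone hammer - handle,weighted,9.9,18.88,21.31,Table 5,True
Golf club head - grinding,unweighted,14.77,19.89,24.79,Table 5,False
Golf club head - grinding,weighted,1.04,2.37,2.59,Table 5,True
Needle scaler,unweighted,73.16,41.22,83.97,Table 5,True
Needle scaler,weighted,11.38,3.45,11.89,Table 5,True
Steel bucking bar B,unweighted,79.94,35.33,87.4,Table 5,True
Steel bucking bar B,weighted,12.07,8.67,14.86,Table 5,True
Tungsten bucking bar E,unweighted,27.09,13.42,30.23,Table 5,True
Tungsten bucking bar E,weighted,5.17,3.96,6.51,Table 5,True
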