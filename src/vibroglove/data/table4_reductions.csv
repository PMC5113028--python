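tool,aw_ms2,u_gel,u_bladder,u_bubble,u_neoprene,w_gel,w_bladder,w_bubble,w_neoprene
Fast Fork-Tines,26.56,1,0,3,3,3,0,4,0
Fast Fork - Wire Mesh,12.15,1,2,3,2,3,2,5,-1
Slow Fork-Tines,7.99,-1,0,1,5,2,2,4,0
Slow Fork - Wire Mesh,3.92,-1,0,2,5,3,2,4,-1
Hand-held Tractor - Rota filling,6.8,4,4,5,-3,4,4,5,-2
Hand-held Tractor - Rota pudding,5.27,3,3,4,-4,4,4,5,-2
Hand-held Tractor - Transportation,8.15,2,2,3,-2,2,2,3,-1
Bench Rammer,30.5,1,0,2,-5,2,0,2,-1
Floor Rammer,23.69,-2,0,-1,0,1,1,0,-1
Pavement Tamper,18.19,-1,-1,0,-2,1,0,1,-1
Impact Wrench A,6.58,-7,-4,-2,19,-2,-1,0,0
Impact Wrench B,2.69,-8,-7,-4,5,1,1,2,-2
Impact Wrench C,9.01,-9,-10,-5,8,-1,-1,1,-5
Impact Wrench D,8.09,-10,-11,-6,6,-3,-3,-1,-8
Rivet A,20.44,-7,-8,-4,13,1,1,3,-2
Rivet B,15.8,-8,-4,-2,0,-3,-2,-1,-8
Rivet C,27.54,-7,-10,-6,10,1,-1,1,-5
Rivet D,29.11,-8,-11,-6,9,2,1,3,-3
Rivet E,13.48,-6,-3,-1,12,-1,0,1,-6
Rivet F,17.58,-8,-10,-5,11,2,1,3,-3
Rivet G,20.55,-5,-2,-2,9,1,0,2,-5
Rivet H,20.65,-5,-3,-1,11,2,0,2,-4
Rivet S1,2.81,-6,-5,-4,3,-2,-2,-2,-7
Rivet S2,2.37,-6,-5,-3,8,0,-1,1,-5
Rivet S3,2.52,-6,-6,-2,11,0,-1,1,-5
Rivet S4,5.22,-8,-8,-4,11,1,1,2,-3
Steel Bucking Bar B,14.86,-12,-16,-9,2,-1,-3,0,-6
Tungsten Bucking Bar E,6.51,-12,-14,-7,0,0,-1,1,-5
CH Bucking Bar,15.39,-9,-14,-7,8,1,1,3,-3
DF Bucking Bar,27.74,-7,-6,-4,3,1,1,3,-4
Foot Bucking Bar,12.5,-15,-18,-10,1,-3,-5,-2,-9
L Bucking Bar,7.65,-11,-11,-7,6,-7,-4,-5,-9
TR Bucking Bar 1,14.34,-13,-14,-8,2,-9,-6,-4,-12
TR Bucking Bar 2,21.24,-3,0,-1,8,4,4,4,-3
Paving Breaker,52.26,0,-4,-1,-1,4,3,5,-2
Clay Spade,27.25,-4,-2,-2,-9,1,0,2,-9
Chipping Hammer B,12.16,-4,-3,1,18,3,4,4,-2
Chipping Hammer A,10.95,-5,0,0,14,5,0,5,-1
Impact Drill,9.08,-10,-10,-6,16,-9,-7,-4,11
Rotary Hammer,18.91,-8,-5,-1,2,3,0,4,-4
Rock Drill,11.7,0,-2,1,7,8,7,7,-1
Stone Hammer - Chisel,19.31,-20,-17,-8,8,-12,-10,-5,-7
Stone Hammer - Handle,21.31,-2,0,-5,4,2,1,0,-5
3kg Impact Drill,11.71,-6,-10,-4,18,-1,0,1,-4
6kg Impact Drill,9.44,-7,-5,-3,12,4,2,4,-3
Needle Scaler,11.89,-14,-12,-6,-4,-16,-10,-6,-17
Scabbler,12.8,7,6,6,-2,9,7,8,-1
PC Sander,9.9,-6,-5,-4,-7,-6,-6,-5,-19
P Air Sander,2.69,-6,-3,-1,22,-3,-2,0,5
Belt Sander,3.8,-5,-1,0,24,-3,-1,0,17
BD Sander,17.8,-6,-3,-7,-16,-4,-2,-7,-20
Orbit Sander,4.79,-7,-7,-3,-6,-2,-4,0,-12
Pavement Cutting Saw,12.12,-6,-4,-6,-12,-4,-3,-5,-16
Miter Saw,5.47,-6,-2,-4,2,-2,1,-4,-11
Jig Saw,6.77,-10,-9,-4,6,-4,-4,0,-10
Circular Saw,6.11,-6,0,-2,13,-2,0,-3,-5
Reciprocating Saw,5.78,-8,-7,-5,14,2,1,2,-1
Chain Saw,9.93,6,4,4,-6,9,5,7,-4
Multi-use Tool,11.84,-8,-3,-1,17,-8,-3,-1,16
Golf Club Head-Grinding,2.59,-5,-7,-3,12,6,4,5,-1
Vertical Grinder ship yard,11.33,-11,-17,-9,15,-6,-10,-4,0
7 In Grinder,6.1,-7,-4,-3,14,3,2,4,-2
4.5 In Grinder,11.99,-4,-7,-5,-5,-1,-3,-1,-13
Electric Angular Grinder,9.99,-4,-7,-2,2,1,-3,2,-9
Angular Grinder,5.47,-6,0,-1,13,-1,0,-1,-3
Die Grinder,1.69,-6,-2,0,19,0,0,1,0
Pencil Grinder,1.57,-5,-14,-8,10,1,0,1,0
Hedge Trimmer,13.48,-4,-1,-3,4,3,3,2,-6
Strimmer,7.11,-6,-6,-5,7,-3,-2,-4,-11
Trimmer,13.48,-4,-1,-3,4,3,3,2,-6
Angular Nutrunner,2.88,-4,-1,-2,6,2,2,3,-2
Straight Nutrunner 1,2.42,-5,-3,-4,5,1,0,1,-1
Straight Nutrunner 2,2.17,-7,-5,-4,2,0,0,1,-3
Straight Nutrunner 3,2.93,-8,-7,-4,2,0,-1,1,-5
Angular Nutrunner 2,16.7,-5,-1,-2,12,0,1,1,-1
Pistol Nutrunner,2.57,-6,-8,-4,11,2,1,2,-1
Pistol Screw Gunn 1,4.19,-4,-4,-1,12,2,1,3,-1
Pistol Screw Gunn 2,5.55,-2,-3,0,2,2,1,3,-1
Pistol Screw Gunn 3,2.99,-4,-2,0,6,2,2,3,-2
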