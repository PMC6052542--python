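name,C,H,O,N,thod,carbon_count,acid_flag,solubility_g_per_L,source
glucose,6,12,6,0,1.065743,6,0,,formula
xylose,5,10,5,0,1.065743,5,0,,formula
formic acid,1,2,2,0,0.347637,1,1,,formula
acetic acid,2,4,2,0,1.065743,2,1,,formula
propionic acid,3,6,2,0,1.511899,3,1,,formula
butyric acid,4,8,2,0,1.815994,4,1,,formula
pentanoic acid,5,10,2,0,2.036560,5,1,,formula
hexanoic acid,6,12,2,0,2.203857,6,1,10.8,formula
heptanoic acid,7,14,2,0,2.335103,7,1,2.4,formula
octanoic acid,8,16,2,0,2.440817,8,1,0.68,formula
ethanol,2,6,1,0,2.083831,2,0,,formula
glycerol,3,8,3,0,1.216149,3,0,,formula
lactic acid,3,6,3,0,1.065743,3,0,,formula
acetamide,2,5,1,1,1.083497,2,0,,formula
protein,,,,,1.5,0,0,,literature
carbohydrate,,,,,1.06,0,0,,literature
unknown,,,,,1.0,0,0,,literature
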