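code,legislation,foodstuff,limit_value,limit_unit
Cd 3.2.5,Reg.1881/2006/CE,Muscle meat of fish,0.05,mg/kg w.w.
Cd 3.2.6,Reg.1881/2006/CE,Muscle meat of listened fish,0.10,mg/kg w.w.
Cd 3.2.8,Reg.1881/2006/CE,Crustaceans,0.50,mg/kg w.w.
Cd 3.2.9,Reg.1881/2006/CE,Bivalve molluscs,1.0,mg/kg w.w.
Cd 3.2.10,Reg.1881/2006/CE,Cephalopods,1.0,mg/kg w.w.
Hg 3.3.1,Reg.1881/2006/CE,Fishery products and muscle meat of fish,0.50,mg/kg w.w.
Hg 3.3.2,Reg.1881/2006/CE,Muscle meat of listened fish,1.0,mg/kg w.w.
Pb 3.1.5,Reg.1881/2006/CE,Muscle meat of fish,0.3,mg/kg w.w.
Pb 3.1.6,Reg.1881/2006/CE,Crustaceans,0.50,mg/kg w.w.
Pb 3.1.7,Reg.1881/2006/CE,Bivalve molluscs,1.5,mg/kg w.w.
Pb 3.1.8,Reg.1881/2006/CE,Cephalopods,1.0,mg/kg w.w.
Dioxins 5.3,Reg.1259/2011/CE,Muscle meat of fish and Bivalve molluscs,3.5,pg/g w.w.
Sum dioxins and dioxin like PCBs 5.3,Reg.1259/2011/CE,Muscle meat of fish and Bivalve molluscs,6.5,pg/g w.w.
Benzo(a)pyrene 6.1.4,Reg.1881/2006/CE,Muscle meat of fish,2.0,µg/kg w.w.
Benzo(a)pyrene 6.1.5,Reg.1881/2006/CE,Crustaceans and Cephalopods,5.0,µg/kg w.w.
Benzo(a)pyrene 6.1.6,Reg.835/2011/CE,Bivalve molluscs,5,µg/kg w.w.
Sum PAH 6.1.6,Reg.835/2011/CE,Bivalve molluscs,30,µg/kg w.w.
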