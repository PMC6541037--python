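class_id,name,n_acyl_positions,backbone,linkage,classification_parents,headgroup_charge,curvature,function_terms,component_terms
PC,phosphatidylcholine,2,glycerol,ester,glycerophospholipids>glycerophosphocholines>diacylglycerophosphocholines,positive_zwitterion,neutral,membrane component,endoplasmic reticulum;plasma membrane;Golgi apparatus
PC O-,ether phosphatidylcholine,2,glycerol,ether_O,glycerophospholipids>glycerophosphocholines>alkylacylglycerophosphocholines,positive_zwitterion,neutral,membrane component,plasma membrane
PC P-,plasmalogen phosphatidylcholine,2,glycerol,ether_P,glycerophospholipids>glycerophosphocholines>alkenylacylglycerophosphocholines,positive_zwitterion,neutral,membrane component,plasma membrane
LPC,lysophosphatidylcholine,1,glycerol,ester,glycerophospholipids>glycerophosphocholines>monoacylglycerophosphocholines,positive_zwitterion,positive,lipid-mediated signaling,endoplasmic reticulum
LPC O-,ether lysophosphatidylcholine,1,glycerol,ether_O,glycerophospholipids>glycerophosphocholines>monoalkylglycerophosphocholines,positive_zwitterion,positive,lipid-mediated signaling,endoplasmic reticulum
PE,phosphatidylethanolamine,2,glycerol,ester,glycerophospholipids>glycerophosphoethanolamines>diacylglycerophosphoethanolamines,positive_zwitterion,negative,membrane component,mitochondrion;endoplasmic reticulum
PE O-,ether phosphatidylethanolamine,2,glycerol,ether_O,glycerophospholipids>glycerophosphoethanolamines>alkylacylglycerophosphoethanolamines,positive_zwitterion,negative,membrane component,plasma membrane
PE P-,plasmalogen phosphatidylethanolamine,2,glycerol,ether_P,glycerophospholipids>glycerophosphoethanolamines>alkenylacylglycerophosphoethanolamines,positive_zwitterion,negative,membrane component,plasma membrane
LPE,lysophosphatidylethanolamine,1,glycerol,ester,glycerophospholipids>glycerophosphoethanolamines>monoacylglycerophosphoethanolamines,positive_zwitterion,positive,lipid-mediated signaling,endoplasmic reticulum
PS,phosphatidylserine,2,glycerol,ester,glycerophospholipids>glycerophosphoserines>diacylglycerophosphoserines,negative,neutral,membrane component;lipid-mediated signaling,plasma membrane
LPS,lysophosphatidylserine,1,glycerol,ester,glycerophospholipids>glycerophosphoserines>monoacylglycerophosphoserines,negative,positive,lipid-mediated signaling,plasma membrane
PG,phosphatidylglycerol,2,glycerol,ester,glycerophospholipids>glycerophosphoglycerols>diacylglycerophosphoglycerols,negative,neutral,membrane component,mitochondrion
LPG,lysophosphatidylglycerol,1,glycerol,ester,glycerophospholipids>glycerophosphoglycerols>monoacylglycerophosphoglycerols,negative,positive,lipid-mediated signaling,mitochondrion
BMP,bis(monoacylglycero)phosphate,2,glycerol,ester,glycerophospholipids>glycerophosphoglycerols>bis(monoacylglycero)phosphates,negative,neutral,membrane component,late endosome
PA,phosphatidic acid,2,glycerol,ester,glycerophospholipids>glycerophosphates>diacylglycerophosphates,negative,negative,lipid-mediated signaling,endoplasmic reticulum
LPA,lysophosphatidic acid,1,glycerol,ester,glycerophospholipids>glycerophosphates>monoacylglycerophosphates,negative,positive,lipid-mediated signaling,endoplasmic reticulum
PI,phosphatidylinositol,2,glycerol,ester,glycerophospholipids>glycerophosphoinositols>diacylglycerophosphoinositols,negative,neutral,membrane component;lipid-mediated signaling,endoplasmic reticulum;Golgi apparatus
LPI,lysophosphatidylinositol,1,glycerol,ester,glycerophospholipids>glycerophosphoinositols>monoacylglycerophosphoinositols,negative,positive,lipid-mediated signaling,endoplasmic reticulum
CL,cardiolipin,4,glycerol,ester,glycerophospholipids>glycerophosphoglycerophosphoglycerols>cardiolipins,negative,negative,membrane component,mitochondrion
SM,sphingomyelin,2,sphingoid,ester,sphingolipids>phosphosphingolipids>sphingomyelins,positive_zwitterion,neutral,membrane component,plasma membrane;lysosome
Cer,ceramide,2,sphingoid,ester,sphingolipids>ceramides>N-acylsphingosines,neutral,negative,lipid-mediated signaling,endoplasmic reticulum;Golgi apparatus
HexCer,hexosylceramide,2,sphingoid,ester,sphingolipids>neutral glycosphingolipids>hexosylceramides,neutral,neutral,membrane component,plasma membrane;Golgi apparatus
Hex2Cer,dihexosylceramide,2,sphingoid,ester,sphingolipids>neutral glycosphingolipids>dihexosylceramides,neutral,neutral,membrane component,plasma membrane;Golgi apparatus
MG,monoacylglycerol,1,glycerol,ester,glycerolipids>monoradylglycerols>monoacylglycerols,neutral,positive,lipid-mediated signaling,endoplasmic reticulum
DG,diacylglycerol,2,glycerol,ester,glycerolipids>diradylglycerols>diacylglycerols,neutral,negative,lipid-mediated signaling,endoplasmic reticulum;Golgi apparatus
TG,triacylglycerol,3,glycerol,ester,glycerolipids>triradylglycerols>triacylglycerols,neutral,,lipid storage,lipid droplet
CE,cholesteryl ester,1,sterol,ester,sterol lipids>sterols>steryl esters,neutral,,lipid storage,lipid droplet
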