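connection	Intro1	1-back	Intro2	2-back	Intro3	3-back	Rest
RFP->RMFG	0.72 (0.3)	0.94 (0.3)	< 0.59 (0.2)	0.96 (0.3)	< 0.22 (0.2)	0.97 (0.3)	< 0.21 (0.1)
LIPS->LIFG	< 0.28 (0.2)	0.42 (0.2)	< 0.45 (0.2)	0.52 (0.2)	0.7 (0.3)	0.34 (0.2)	0.32 (0.3)
LMFG->LIFG	0.45 (0.2)	0.4 (0.2)	0.69 (0.2)	< 0.51 (0.3)	< 1.08 (0.4)	0.31 (0.1)	0.34 (0.1)
LFP->RFP	0.43 (0.3)	< 0.82 (0.2)	< 0.81 (0.2)	< 0.82 (0.2)	0.34 (0.2)	0.49 (0.1)	0.36 (0.2)
LFP->LMFG	< 0.93 (0.2)	0.69 (0.2)	0.33 (0.2)	0.26 (0.2)	< 0.89 (0.2)	0.38 (0.2)	0.41 (0.2)
ACC->LOFc	< 0.89 (0.2)	0.76 (0.2)	0.51 (0.2)	0.77 (0.2)	0.78 (0.2)	< 0.86 (0.2)	0.43 (0.2)
LOFc->Rins	0.86 (0.2)	0.74 (0.1)	< 0.41 (0.2)	0.76 (0.1)	0.66 (0.2)	0.78 (0.1)	< 0.47 (0.1)
Lbas->Lthal	1.07 (0.3)	1.08 (0.3)	< 0.33 (0.2)	0.97 (0.2)	1.03 (0.4)	< 0.29 (0.1)	< 0.48 (0.2)
Rprecun->LLOCs	< 0.59 (0.3)	0.68 (0.2)	0.75 (0.3)	0.71 (0.2)	0.5 (0.3)	< 0.61 (0.2)	0.70 (0.2)
RIPS->LIPS	0.29 (0.2)	< 0.61 (0.2)	0.51 (0.1)	0.82 (0.2)	0.78 (0.2)	0.65 (0.1)	0.81 (0.2)
RSFG->LSFG	0.74 (0.2)	0.4 (0.2)	< 0.91 (0.2)	0.5 (0.2)	0.67 (0.2)	< 0.61 (0.1)	< 0.85 (0.1)
LIFG->ACC	0.33 (0.3)	0.61 (0.2)		0.39 (0.2)	0.39 (0.2)	0.24 (0.1)	0.19 (0.2)
LSFG->LMFG	0.99 (0.4)	< 0.27 (0.1)	0.66 (0.3)	0.34 (0.2)		0.62 (0.1)	0.6 (0.2)
RIPS->RLOCs		0.94 (0.2)	0.96 (0.3)	0.96 (0.3)	0.78 (0.3)	0.92 (0.2)	0.73 (0.3)
RIPS->RFP	0.28 (0.3)	< 0.24 (0.1)			0.39 (0.2)	< 0.64 (0.2)	0.22 (0.2)
LIPS-LSFG	< 0.17 (0.2)	0.17 (0.1)		0.39 (0.2)			0.74 (0.2)
RSFG->RFP	0.32 (0.3)					< 0.33 (0.2)	0.21 (0.2)
LLOCs->RLOCs					0.25 (0.2)	< 0.39 (0.3)	0.27 (0.2)
RSFG->ACC							0.75 (0.2)
RFP->ACC	< 0.00 (0.3)*	0.34 (0.1)*			0.28 (0.1)*	< 0.5 (0.2)*	
RSFG->RIPS		0.18 (0.2)	0.69 (0.2)*	< 0.85 (0.2)*	0.63 (0.4)		
ACC->Lbas	0.66 (0.1)		0.37 (0.2)*	0.59 (0.2)*	0.66 (0.3)*	0.38 (0.2)*	
LSFG->ACC			0.9 (0.3)		0.35 (0.2)*	< 0.76 (0.2)*	
LIPS->LLOCs		< 0.46 (0.1)			0.55 (0.5)*	0.82 (0.4)*	
RIPS->Rprecun				1.19 (0.3)	< 0.17 (0.2)*	0.48 (0.3)*	
Rcereb->Rprecun			0.21 (0.3)			0.13 (0.4)	
RLOCs->Rprecun	0.56 (0.4)		0.86 (0.4)				
LFP->LIPS						0.16 (0.1)	
LFP->Rprecun		0.82 (0.3)					
LMFG->RMFG	0.34 (0.3)						
Rcereb->LIPS		0.13 (0.1)					
RIPS->Rins					0.19 (0.2)		
RLOCs->LIPS	0.16 (0.1)						
RMFG->LSFG					0.07 (0.2)		
Rprecun->Rcereb				0.74 (0.3)			
Rprecun->RFP	0.08 (0.2)						
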