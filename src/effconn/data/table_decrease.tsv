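connection	Intro1	1-back	Intro2	2-back	Intro3	3-back	Rest
LPCCa->LPCCp	0.59 (0.4)	1.1 (0.3)	< 0.17 (0.1)	0.55 (0.3)	0.83 (0.5)	1.13 (0.2)	1.04 (0.3)
LPCCp->LFmed	< 0.48 (0.4)	0.64 (0.2)	0.52 (0.3)	< 0.54 (0.2)	0.5 (0.3)	0.73 (0.2)	0.73 (0.1)
RFP->LFmed	< 0.59 (0.2)	0.25 (0.2)	0.35 (0.3)	0.73 (0.2)	0.42 (0.4)	< 0.58 (0.2)	< 0.48 (0.2)
BJuxt->LPCCa	< 1.3 (0.4)	< 0.82 (0.2)	0.52 (0.1)	0.63 (0.1)	0.61 (0.1)	0.63 (0.1)	0.55 (0.1)
BJuxt->LPostPrec	0.61 (0.2)	0.6 (0.2)	0.61 (0.2)	0.59 (0.2)	< 1.06 (0.3)	0.62 (0.2)	< 0.55 (0.3)
BJuxt->RPrec	0.73 (0.2)	< 0.39 (0.1)	0.74 (0.3)	0.7 (0.2)	0.26 (0.2)	0.69 (0.2)	0.37 (0.2)
RLOCi->LOccipP	0.69 (0.2)	0.71 (0.3)	0.7 (0.3)	0.69 (0.2)	0.64 (0.4)	< 0.31 (0.2)	0.67 (0.2)
RParOperc->LPlanPol	< 0.72 (0.2)	0.63 (0.2)	< 1.04 (0.2)	< 0.67 (0.1)	0.47 (0.2)	0.51 (0.1)	0.74 (0.1)
RPrec->RPosta	0.74 (0.3)	0.77 (0.2)	0.78 (0.2)	0.76 (0.2)	< 0.35 (0.2)	0.76 (0.2)	0.71 (0.2)
RPrec->RPostp	0.84 (0.2)	0.46 (0.3)	0.81 (0.2)	0.72 (0.2)	< 0.38 (0.2)	0.76 (0.2)	< 0.46 (0.1)
BJuxt->RParOperc	0.31 (0.2)	0.76 (0.1)		0.32 (0.1)			< 0.52 (0.1)
RPostp->RPostm	1.17 (0.3)	< 0.31 (0.2)			1.1 (0.4)		1.09 (0.4)
RParOperc->RPlanPol				0.86 (0.1)		0.86 (0.2)	< 0.55 (0.2)
RTP->RPlanPol	0.18 (0.2)				0.34 (0.2)		< 0.72 (0.5)
LPCCa->RLOCi					0.95 (0.4)		0.80 (0.2)
RPostp->LPCCa							0.1 (0.09)
RParOperc->RLOCi	0.64 (0.3)		0.58 (0.4)*	0.64 (0.2)*		0.48 (0.2)	
RPlanPol->LPlanPola	< 0.9 (0.2)*	0.14 (0.1)*	0.29 (0.2)		0.15 (0.1)		
BJuxt->LPlanPol			0.47 (0.1)		0.24 (0.1)*	0.29 (0.1)*	
RPrec->RPostm			1.12 (0.3)*	1.02 (0.4)*		1.05 (0.4)	
RTP->LFmed		0.11 (0.1)				0.17 (0.2)	
RFP->RTP			0.85 (0.6)				
BJuxt->RTP				0.7 (0.5)			
RLOCi->BJuxt		0.06 (0.1)					
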