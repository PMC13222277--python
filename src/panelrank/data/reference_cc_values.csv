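criterion,cc_relevance,rank_relevance,cc_applicability,rank_applicability,mu,rank_unified
C2,0.75,1,0.61,4,0.68,3
C3,0.74,2,0.59,10,0.67,5
C21,0.73,3,0.67,1,0.70,1
C25,0.73,4,0.55,19,0.64,12
C5,0.73,5,0.59,9,0.66,6
C16,0.73,6,0.63,3,0.68,4
C27,0.72,7,0.59,8,0.66,7
C10,0.72,8,0.58,11,0.65,9
C23,0.72,9,0.65,2,0.69,2
C24,0.72,10,0.57,13,0.65,10
C22,0.71,11,0.61,5,0.66,8
C26,0.70,12,0.55,20,0.63,14
C17,0.69,13,0.60,6,0.65,11
C4,0.67,14,0.53,21,0.60,16
C8,0.67,15,0.60,7,0.64,13
C6,0.64,16,0.57,15,0.61,15
C7,0.62,17,0.57,14,0.60,18
C1,0.61,18,0.56,18,0.59,19
C9,0.61,19,0.58,12,0.60,17
C19,0.60,20,0.56,17,0.58,20
C13,0.57,21,0.56,16,0.57,21
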