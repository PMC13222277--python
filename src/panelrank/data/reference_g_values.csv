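criterion,relevance,applicability
C1,6.356,5.231
C2,6.843,5.448
C3,6.787,5.323
C4,6.453,5.025
C5,6.731,5.236
C6,6.341,5.282
C7,6.325,5.304
C8,6.512,5.434
C9,5.603,5.277
C10,6.722,5.323
C11,5.485,4.465
C12,5.485,4.786
C13,5.491,5.277
C14,5.455,5.049
C15,5.477,4.570
C16,6.731,5.491
C17,6.580,5.440
C18,5.108,4.577
C19,6.271,5.271
C20,5.251,5.072
C21,6.777,5.672
C22,6.615,5.383
C23,6.700,5.595
C24,6.713,5.317
C25,6.731,5.193
C26,6.632,5.162
C27,6.713,5.290
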