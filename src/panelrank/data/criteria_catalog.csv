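code,label,axis,aspect,granularity
C1,Irregular meal times,etiology,behavioral,individual
C2,Unbalanced diet and/or diet based on ultra-processed and hyperpalatable foods,etiology,behavioral,individual
C3,Excessive consumption of sugar and sugary drinks,etiology,behavioral,individual
C4,Excessive alcohol consumption,etiology,behavioral,individual
C5,Sedentary lifestyle (low physical activity),etiology,behavioral,individual
C6,"Sleep cycle (sleep deprivation, circadian dysregulation)",etiology,behavioral,individual
C7,Chronic and/or occupational stress affecting eating habits,etiology,psychological,individual
C8,Anxiety and emotional disorders,etiology,psychological,individual
C9,Low self-esteem related to body image,etiology,psychological,individual
C10,Emotional eating,etiology,psychological,individual
C11,"Genetic predisposition, rare genetic obesity and polymorphisms",etiology,biological,individual
C12,Hormonal imbalances,etiology,biological,individual
C13,Endocrine diseases,etiology,biological,individual
C14,Metabolic alterations (reduced basal energy expenditure),etiology,biological,individual
C15,"Epigenetics, intrauterine programming and gut microbiota",etiology,biological,individual
C16,Obesogenic environment,etiology,environmental,individual
C17,Family influence and cultural norms,etiology,environmental,individual
C18,Exposure to endocrine disruptors,etiology,environmental,individual
C19,Socioeconomic inequality affecting access to healthy food and physical activity,etiology,environmental,individual
C20,"Urban infrastructure, school environment and public policies",etiology,environmental,individual
C21,Consequences - biological aspects,consequence,biological,aggregated
C22,Consequences - psychological aspects,consequence,psychological,aggregated
C23,Consequences - behavioral aspects,consequence,behavioral,aggregated
C24,Adherence - motivation to start treatment,adherence,aggregated,aggregated
C25,Adherence - barriers to starting treatment,adherence,aggregated,aggregated
C26,Adherence - motivation to drop out of treatment,adherence,aggregated,aggregated
C27,Adherence - motivation to remain in treatment,adherence,aggregated,aggregated
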