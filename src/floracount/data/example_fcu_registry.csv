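species,fcu_type,flowers_per_fcu,fcus_per_plant
Papaver rhoeas,solitary_flower,1,3.5
Caltha palustris,single_flower,1,12
Bellis perennis,capitulum,100,6
Leucanthemum vulgare,capitulum,250,4
Hypochaeris radicata,capitulum,90,8
Dactylorhiza praetermissa,spike,40,1
Salvia pratensis,verticillaster,6,10
Lotus corniculatus,cyme,4,15
Cicuta virosa,compound_umbel,500,5
Tanacetum vulgare,corymb_of_capitula,900,7
Achillea millefolium,corymb,150,9
Buttercup*,single_flower,1,8
Chamomile*,capitulum,120,10
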