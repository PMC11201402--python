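study_id,clinical_diagnosis,gh_treatment,gh_response,spont_growth_norm,spont_igf1_norm
IGF22,"ISS, constitutional delay, familial short stature",Y,Good laboratory and clinical response,N,N
IGF40,Genetic condition: 40 megabase deletion on chromosome 13,N,N/A,N,Y
IGF43,"ISS, intrauterine growth restriction",Y,Good laboratory and clinical response,N,N
IGF50,ISS,N,N/A,N,Y
IGF05,"ISS, constitutional delay",N,N/A,N,Y
IGF08,"Familial short stature, constitutional delay",Y,Good laboratory response; poor clinical response,N,N
IGF49,Constitutional delay,N,N/A,N,Y
IGF37,"Constitutional delay, transient prepubertal slowing of growth with resumption of normal growth velocity at puberty onset",N,N/A,Y,Y
IGF19,ISS,Y,Good laboratory and clinical response,N,N
IGF20,"ISS, constitutional delay, familial short stature",Y,Good laboratory and clinical response,N,N
IGF39,Hemihypertrophy syndrome,N,N/A,Y,Y
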