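drug_code,drug_name,category1,category2,priority,is_supplementary,gap_class,default_coverage_days
secukinumab,Secukinumab,Biologics,IL-17 inhibitors,1,False,biologic,28
ixekizumab,Ixekizumab,Biologics,IL-17 inhibitors,1,False,biologic,28
brodalumab,Brodalumab,Biologics,IL-17 inhibitors,1,False,biologic,14
adalimumab,Adalimumab,Biologics,TNF-α inhibitors,2,False,biologic,14
infliximab,Infliximab,Biologics,TNF-α inhibitors,2,False,biologic,56
certolizumab_pegol,Certolizumab pegol,Biologics,TNF-α inhibitors,2,False,biologic,14
guselkumab,Guselkumab,Biologics,IL-23 inhibitors,3,False,biologic,56
risankizumab,Risankizumab,Biologics,IL-23 inhibitors,3,False,biologic,84
ustekinumab,Ustekinumab,Biologics,IL-23 inhibitors,3,False,biologic,84
etretinate,Etretinate,Systemic oral medications,Etretinate,4,False,oral,30
cyclosporin,Cyclosporin,Systemic oral medications,Cyclosporin,5,False,oral,30
apheresis,Apheresis/plasma exchange,Apheresis/plasma exchange,Apheresis/plasma exchange,6,False,other,1
systemic_corticosteroid,Systemic corticosteroids,Systemic oral medications,Systemic corticosteroids,7,False,oral,30
apremilast,Apremilast,Systemic oral medications,Apremilast,8,False,oral,30
methotrexate,Methotrexate,Systemic oral medications,Methotrexate,9,False,oral,7
topical_corticosteroid,Topical corticosteroids,Topical therapy,Topical therapy,10,True,other,30
topical_vitamin_d3,Topical vitamin D3,Topical therapy,Topical therapy,10,True,other,30
antihistamine,Antihistamines,Systemic oral medications,Other oral medications,11,True,oral,30
immunosuppressant,Immunosuppressants,Systemic oral medications,Other oral medications,11,True,oral,30
nsaid,Non-steroidal anti-inflammatory drugs,Systemic oral medications,Other oral medications,11,True,oral,30
arthritis_treatment,Arthritis treatment,Arthritis treatment,Arthritis treatment,12,True,other,30
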