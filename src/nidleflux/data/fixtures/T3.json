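{
"metabolites":[
{
"id":"A",
"name":"",
"compartment":"c",
"formula":"C6H12O6"
},
{
"id":"P",
"name":"",
"compartment":"c",
"formula":"C3H4O3"
}
],
"reactions":[
{
"id":"BIOMASS",
"name":"",
"metabolites":{
"P":-1.0
},
"lower_bound":0.0,
"upper_bound":1000.0,
"gene_reaction_rule":"",
"objective_coefficient":1.0
},
{
"id":"EX_A",
"name":"",
"metabolites":{
"A":1.0
},
"lower_bound":0.0,
"upper_bound":1000.0,
"gene_reaction_rule":""
},
{
"id":"R1",
"name":"",
"metabolites":{
"A":-1.0,
"P":1.0
},
"lower_bound":0.0,
"upper_bound":1000.0,
"gene_reaction_rule":"g1"
},
{
"id":"R2",
"name":"",
"metabolites":{
"A":-1.0,
"P":1.0
},
"lower_bound":0.0,
"upper_bound":1000.0,
"gene_reaction_rule":"g2"
}
],
"genes":[
{
"id":"g1",
"name":""
},
{
"id":"g2",
"name":""
}
],
"id":"T3",
"compartments":{
"c":""
},
"version":"1"
}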