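individual_id,site_id,species,phenophase,date,status
A,s1,sp1,breaking_leaf_buds,2015-03-01,no
A,s1,sp1,breaking_leaf_buds,2015-03-21,yes
B,s1,sp1,breaking_leaf_buds,2015-03-31,no
B,s1,sp1,breaking_leaf_buds,2015-04-10,yes
C,s1,sp1,breaking_leaf_buds,2015-02-19,no
C,s1,sp1,breaking_leaf_buds,2015-04-10,yes
E,s1,sp1,breaking_leaf_buds,2015-03-10,unsure
E,s1,sp1,breaking_leaf_buds,2015-03-19,no
E,s1,sp1,breaking_leaf_buds,2015-03-21,yes
F,s1,sp1,breaking_leaf_buds,2015-06-19,no
F,s1,sp1,breaking_leaf_buds,2015-06-29,yes
G,s2,sp2,open_flowers,2015-07-19,no
G,s2,sp2,open_flowers,2015-07-29,yes
H,s2,sp2,open_flowers,2015-07-31,no
H,s2,sp2,open_flowers,2015-08-08,yes
I,s1,sp1,breaking_leaf_buds,2015-03-31,no
I,s1,sp1,breaking_leaf_buds,2015-04-01,yes
J,s1,sp1,breaking_leaf_buds,2015-04-10,no
J,s1,sp1,breaking_leaf_buds,2015-04-15,no
J,s1,sp1,breaking_leaf_buds,2015-04-15,yes
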