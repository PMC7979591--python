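comparison,row_method,col_method,row_class,col_class,count
henninger_vs_wood,henninger,wood,yes,yes,134
henninger_vs_wood,henninger,wood,yes,no,0
henninger_vs_wood,henninger,wood,no,yes,0
henninger_vs_wood,henninger,wood,no,no,252
henninger_vs_garbowski,henninger,garbowski,yes,yes,134
henninger_vs_garbowski,henninger,garbowski,yes,no,0
henninger_vs_garbowski,henninger,garbowski,no,yes,6
henninger_vs_garbowski,henninger,garbowski,no,no,246
henninger_vs_hankins,henninger,hankins,yes,yes,106
henninger_vs_hankins,henninger,hankins,yes,no,28
henninger_vs_hankins,henninger,hankins,no,yes,0
henninger_vs_hankins,henninger,hankins,no,no,252
garbowski_vs_wood,garbowski,wood,yes,yes,134
garbowski_vs_wood,garbowski,wood,yes,no,6
garbowski_vs_wood,garbowski,wood,no,yes,0
garbowski_vs_wood,garbowski,wood,no,no,246
garbowski_vs_hankins,garbowski,hankins,yes,yes,106
garbowski_vs_hankins,garbowski,hankins,yes,no,34
garbowski_vs_hankins,garbowski,hankins,no,yes,0
garbowski_vs_hankins,garbowski,hankins,no,no,246
hankins_vs_wood,hankins,wood,yes,yes,106
hankins_vs_wood,hankins,wood,yes,no,0
hankins_vs_wood,hankins,wood,no,yes,28
hankins_vs_wood,hankins,wood,no,no,252
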