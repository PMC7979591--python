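comparison,row_method,col_method,row_class,col_class,count
henninger_vs_wood,henninger,wood,0,0,252
henninger_vs_wood,henninger,wood,0,1,0
henninger_vs_wood,henninger,wood,0,2,0
henninger_vs_wood,henninger,wood,0,3,0
henninger_vs_wood,henninger,wood,1,0,0
henninger_vs_wood,henninger,wood,1,1,110
henninger_vs_wood,henninger,wood,1,2,1
henninger_vs_wood,henninger,wood,1,3,0
henninger_vs_wood,henninger,wood,2,0,0
henninger_vs_wood,henninger,wood,2,1,0
henninger_vs_wood,henninger,wood,2,2,22
henninger_vs_wood,henninger,wood,2,3,1
henninger_vs_wood,henninger,wood,3,0,0
henninger_vs_wood,henninger,wood,3,1,0
henninger_vs_wood,henninger,wood,3,2,0
henninger_vs_wood,henninger,wood,3,3,0
henninger_vs_garbowski,henninger,garbowski,0,0,246
henninger_vs_garbowski,henninger,garbowski,0,1,6
henninger_vs_garbowski,henninger,garbowski,0,2,0
henninger_vs_garbowski,henninger,garbowski,0,3,0
henninger_vs_garbowski,henninger,garbowski,1,0,0
henninger_vs_garbowski,henninger,garbowski,1,1,96
henninger_vs_garbowski,henninger,garbowski,1,2,15
henninger_vs_garbowski,henninger,garbowski,1,3,0
henninger_vs_garbowski,henninger,garbowski,2,0,0
henninger_vs_garbowski,henninger,garbowski,2,1,0
henninger_vs_garbowski,henninger,garbowski,2,2,18
henninger_vs_garbowski,henninger,garbowski,2,3,5
henninger_vs_garbowski,henninger,garbowski,3,0,0
henninger_vs_garbowski,henninger,garbowski,3,1,0
henninger_vs_garbowski,henninger,garbowski,3,2,0
henninger_vs_garbowski,henninger,garbowski,3,3,0
henninger_vs_hankins,henninger,hankins,0,0,252
henninger_vs_hankins,henninger,hankins,0,1,0
henninger_vs_hankins,henninger,hankins,0,2,0
henninger_vs_hankins,henninger,hankins,0,3,0
henninger_vs_hankins,henninger,hankins,1,0,28
henninger_vs_hankins,henninger,hankins,1,1,82
henninger_vs_hankins,henninger,hankins,1,2,1
henninger_vs_hankins,henninger,hankins,1,3,0
henninger_vs_hankins,henninger,hankins,2,0,0
henninger_vs_hankins,henninger,hankins,2,1,0
henninger_vs_hankins,henninger,hankins,2,2,22
henninger_vs_hankins,henninger,hankins,2,3,1
henninger_vs_hankins,henninger,hankins,3,0,0
henninger_vs_hankins,henninger,hankins,3,1,0
henninger_vs_hankins,henninger,hankins,3,2,0
henninger_vs_hankins,henninger,hankins,3,3,0
garbowski_vs_wood,garbowski,wood,0,0,246
garbowski_vs_wood,garbowski,wood,0,1,0
garbowski_vs_wood,garbowski,wood,0,2,0
garbowski_vs_wood,garbowski,wood,0,3,0
garbowski_vs_wood,garbowski,wood,1,0,6
garbowski_vs_wood,garbowski,wood,1,1,96
garbowski_vs_wood,garbowski,wood,1,2,0
garbowski_vs_wood,garbowski,wood,1,3,0
garbowski_vs_wood,garbowski,wood,2,0,0
garbowski_vs_wood,garbowski,wood,2,1,14
garbowski_vs_wood,garbowski,wood,2,2,19
garbowski_vs_wood,garbowski,wood,2,3,0
garbowski_vs_wood,garbowski,wood,3,0,0
garbowski_vs_wood,garbowski,wood,3,1,0
garbowski_vs_wood,garbowski,wood,3,2,4
garbowski_vs_wood,garbowski,wood,3,3,1
garbowski_vs_hankins,garbowski,hankins,0,0,246
garbowski_vs_hankins,garbowski,hankins,0,1,0
garbowski_vs_hankins,garbowski,hankins,0,2,0
garbowski_vs_hankins,garbowski,hankins,0,3,0
garbowski_vs_hankins,garbowski,hankins,1,0,34
garbowski_vs_hankins,garbowski,hankins,1,1,68
garbowski_vs_hankins,garbowski,hankins,1,2,0
garbowski_vs_hankins,garbowski,hankins,1,3,0
garbowski_vs_hankins,garbowski,hankins,2,0,0
garbowski_vs_hankins,garbowski,hankins,2,1,14
garbowski_vs_hankins,garbowski,hankins,2,2,19
garbowski_vs_hankins,garbowski,hankins,2,3,0
garbowski_vs_hankins,garbowski,hankins,3,0,0
garbowski_vs_hankins,garbowski,hankins,3,1,0
garbowski_vs_hankins,garbowski,hankins,3,2,4
garbowski_vs_hankins,garbowski,hankins,3,3,1
hankins_vs_wood,hankins,wood,0,0,252
hankins_vs_wood,hankins,wood,0,1,28
hankins_vs_wood,hankins,wood,0,2,0
hankins_vs_wood,hankins,wood,0,3,0
hankins_vs_wood,hankins,wood,1,0,0
hankins_vs_wood,hankins,wood,1,1,82
hankins_vs_wood,hankins,wood,1,2,0
hankins_vs_wood,hankins,wood,1,3,0
hankins_vs_wood,hankins,wood,2,0,0
hankins_vs_wood,hankins,wood,2,1,0
hankins_vs_wood,hankins,wood,2,2,23
hankins_vs_wood,hankins,wood,2,3,0
hankins_vs_wood,hankins,wood,3,0,0
hankins_vs_wood,hankins,wood,3,1,0
hankins_vs_wood,hankins,wood,3,2,0
hankins_vs_wood,hankins,wood,3,3,1
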