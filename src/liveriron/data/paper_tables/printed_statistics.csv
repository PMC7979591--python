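comparison,scheme,statistic,value
henninger_vs_wood,yesno,overall_agreement_pct,100.00
henninger_vs_garbowski,yesno,overall_agreement_pct,98.45
henninger_vs_hankins,yesno,overall_agreement_pct,92.75
garbowski_vs_wood,yesno,overall_agreement_pct,98.45
garbowski_vs_hankins,yesno,overall_agreement_pct,91.19
hankins_vs_wood,yesno,overall_agreement_pct,92.75
henninger_vs_wood,easl,overall_agreement_pct,99.48
henninger_vs_garbowski,easl,overall_agreement_pct,93.26
henninger_vs_hankins,easl,overall_agreement_pct,92.23
garbowski_vs_wood,easl,overall_agreement_pct,93.78
garbowski_vs_hankins,easl,overall_agreement_pct,86.53
hankins_vs_wood,easl,overall_agreement_pct,92.75
henninger_vs_wood,yesno,kappa,1.000
henninger_vs_garbowski,yesno,kappa,0.966
henninger_vs_hankins,yesno,kappa,0.832
garbowski_vs_wood,yesno,kappa,0.966
garbowski_vs_hankins,yesno,kappa,0.799
hankins_vs_wood,yesno,kappa,0.832
henninger_vs_wood,easl,kappa,0.989
henninger_vs_garbowski,easl,kappa,0.866
henninger_vs_hankins,easl,kappa,0.832
garbowski_vs_wood,easl,kappa,0.877
garbowski_vs_hankins,easl,kappa,0.717
hankins_vs_wood,easl,kappa,0.843
henninger_vs_wood,yesno,kappa_se,0.000
henninger_vs_garbowski,yesno,kappa_se,0.014
henninger_vs_hankins,yesno,kappa_se,0.030
garbowski_vs_wood,yesno,kappa_se,0.014
garbowski_vs_hankins,yesno,kappa_se,0.032
hankins_vs_wood,yesno,kappa_se,0.030
henninger_vs_wood,easl,kappa_se,0.007
henninger_vs_garbowski,easl,kappa_se,0.024
henninger_vs_hankins,easl,kappa_se,0.029
garbowski_vs_wood,easl,kappa_se,0.023
garbowski_vs_hankins,easl,kappa_se,0.034
hankins_vs_wood,easl,kappa_se,0.029
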