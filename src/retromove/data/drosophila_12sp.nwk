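((((((Dmel,(Dsim,Dsec)),(Dyak,Dere)),Dana),(Dpse,Dper)),Dwil),((Dvir,Dmoj),Dgri));
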