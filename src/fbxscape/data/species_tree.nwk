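(Cr,(Pp,(Sm,(((Os,Bd),(Sb,Zm)),(Mg,(Vv,((((Gm,Mt),Cs),((Me,Rc),Pt)),(Cp,(At,Al)))))))));
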