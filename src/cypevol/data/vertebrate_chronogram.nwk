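(((((((((Hosa:6,Patr:6):23,Mamu:29):14,Caja:43):47,(Mumu:21,Rano:21):69):6,(Bota:78,Cafa:78):18):64,Modo:160):152,((Gaga:98,Tagu:98):182,Anca:280):32):40,Xetr:352):48,(Orla:320,Dare:320):80);
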