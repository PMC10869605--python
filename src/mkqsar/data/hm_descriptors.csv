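symbol,meaning,coefficient
MENANNB,Min e-n attraction for a N-N bond,0.54386
MEEROA,Min e-e repulsion for a O atom,-0.19081
MRECCB,Max resonance energy for a C-C bond,0.45861
MBCM,Max bonding contribution of a MO,7.2924
ANRINA,Avg nucleoph. react. index for a N atom,-112.51
KA (O3),Kier shape index (order 3),-0.58196
HDH/T (QCP),HA dependent HDCA-2/TMSA [Quantum-Chemical PC],-192.22
MRECHB,Max resonance energy for a C-H bond,-7.1692
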