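gene	fc_single	sig_single	fc_double	sig_double
Angptl4	9.5	True	14.0	True
Ifitm1	3.0	True	14.0	True
Ifi209	NA	False	25.0	True
Phlda2	10.0	True	16.0	True
Klk1	12.0	True	18.0	True
Pdpn	3.2	True	13.0	True
Akr1b8	4.0	True	30.0	True
Acat2	1.4	False	12.0	True
Tubb6	8.5	True	12.5	True
Oas1a	2.6	True	11.0	True
Hrh2	1.5	False	10.0	True
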