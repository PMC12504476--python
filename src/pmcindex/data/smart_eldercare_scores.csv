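primary,P1,P2,P3,P4,P5,P6,P7,P8,P9,P10
X1,111,111,101,101,101,111,101,101,101,101
X2,111,111,111,111,111,111,111,111,111,111
X3,110,011,001,100,001,011,101,001,101,001
X4,111,101,111,001,101,111,011,011,111,011
X5,11111,01110,11110,01110,01110,11110,01110,01110,01110,11110
X6,1111,1111,1111,1111,1111,1111,1111,1111,1111,1111
X7,111,111,111,111,111,111,111,111,111,111
X8,11111,11101,01111,01111,01111,11111,01111,00111,11111,01111
X9,1111,1110,1110,1010,1111,1111,1010,1110,1111,1110
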