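AS 1 2

CO contig1 20 2 0 U
ACGTACGTACGTACGTACGT

AF read1 U 1
AF read2 C 5

RD read1 12 0 0
ACGTACGTACGT
QA 1 12 1 12

RD read2 16 0 0
ACGTACGTACGTACGT
QA 1 16 1 16

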