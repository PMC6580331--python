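gene	allele	variants	function
NUDT15	*1	.	normal
NUDT15	*2	13:48611918:G:GGAGTC;13:48619855:C:T	no_function
NUDT15	*3	13:48619855:C:T	no_function
NUDT15	*4	13:48619856:G:A	no_function
NUDT15	*5	13:48611934:G:A	no_function
NUDT15	*6	13:48611918:G:GGAGTC	no_function
TPMT	*1	.	normal
TPMT	*1S	6:18139228:A:G	normal
TPMT	*3C	6:18130918:T:C	no_function
TPMT	*6	6:18139243:T:A	decreased
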