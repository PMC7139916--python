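>4EBP1_NT|Q13541 region_start=18 4E-BP1 T37/T46 region
TRRVVLGDGVQLPPGDYSTTPGGTLFSTTPGGTR
>4EBP1_MID|Q13541 region_start=63 4E-BP1 S65/T70 region
RNSPVTKTPPRDLPTIPGVTSPSSDEPPMEASQSHLRN
>4EBP1_CT|Q13541 region_start=94 4E-BP1 C-terminal region
SQSHLRNSPEDKRAGGEESQFEMDI
>CMET|P08581 region_start=1227 hepatocyte growth factor receptor activation loop
RDMYDKEYYSVHNKTGAK
>RPS6|P62753 region_start=230 ribosomal protein S6 C-terminal tail
KRRRLSSLRASTSKSESSQK
>ERK2|P28482 region_start=172 MAPK1 activation loop
RVADPDHDHTGFLTEYVATRW
>ERK1|P27361 region_start=189 MAPK3 activation loop
RIADPEHDHTGFLTEYVATRW
>MTOR|P42345 region_start=2443 mTOR S2448 region
RTRTDSYSAGQSVEILDGVELGEPAHK
>CTNNB1|P35222 region_start=672 beta-catenin S675 region
KRLSVELTSSLFRT
>AKT1|P31749 region_start=465 AKT1 C-terminal region
RRPHFPQFSYSASGTA
>BAD|Q92934 region_start=71 BAD S75 region
SRHSSYPAGTEDDEGMGEEPSPFRG
>STAT3|P40763 region_start=685 STAT3 Y705 region
KYCRPESQEHPEADPGSAAPYLKT
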