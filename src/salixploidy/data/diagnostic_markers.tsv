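marker_id	forward_primer	reverse_primer	amplified	parental_cross	pic
WSSR_11	TTTATAATGGCCATGAGCTT	TCACTAGGTCCTGGAACATC	1	ABxBC	0.54
WSSR_33	GTCATTTACAGGTCTGGCAT	GAGGTTGATGTTTGGTAAGG	1	ABxBC	0.71
WSSR_34	CCCTAGAAAGGAAGGACAAT	CAATGAGTTTGTGATGGTGA	1	ABxBC	0.62
WSSR_88	CACAAATCTTATTGGAAAAC	TTACTACTGATGCTGTTC	1	ABxCD	0.76
WSSR_89	TTGGCAGTTATGTCTCCA	AGTTTGTCCAAGTGTCCC	1	ABxBC	0.57
WSSR_91	CATCGTGCCCAGTAAGGA	ACATAGGAAGCGGGTGGT	1	ABxCD	0.54
WSSR_94	ACAAGGCATCAAAGTAGCA	CTCCAGGAGATCCAAGACG	1	ABxBC	0.68
WSSR_100	GCAAAAGCCAAAAGGAGA	AACCAGCAGAGGAAAGTG	1	ABxCD	0.79
WSSR_124	TGCTCTGAAAGATCTACGGT	AACCACATTGATTCTTCCAC	1	ABxCD	0.67
WSSR_173	TTATTGCTGGAAAGGTTG	TTCGTGTCTTTAGGGTCT	1	ABxBC	0.69
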