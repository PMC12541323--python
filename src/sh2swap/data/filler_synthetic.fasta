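>filler_synthetic synthetic stand-in for phage-genome padding sequence; BsaI-free on both strands
CAGACCTCACAGTCTCATATCCCCGTCGAGTTCAAGTTATAAGAATGGTCTTTGCTAGTA
TCGGTGCTCATCTCCACCAGGTATGGTCGGTTATCGTGCGCAAGAAGCAAAGGGATGGGG
CCATCCTGGACATTAAACCGCGGGAACGATCCTTATCGATGATTAGACTAGCATTATCAC
TGGATGGGCACTGGGGAGGGGACCAGAATTTGGGTCTTGAACTAAATTGCCACGCAGACA
GGGGTAGAAACACCCGCTAAAGGTCAGCAAAGAACTCTTCTAGGCAATTTAAGATACTTG
TAACAGGTTGTACAAAGGGTACGTTGATTAAGTCCGTTCTCAATGAGCGGTTCGACTAGA
AATGATGACCTACTAATAGGGATGAGTGATCGGACTTTATAGCGCCCCCGCGGGGAAGAG
TTACGGGTTCCTGGGGATCGGAGCCCACGTGGAGCCGGGCGAGATGCTCTATGTATCTAT
GCTCCCCGTAGAGCCGTTCT
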