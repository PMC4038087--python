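; Synthetic stand-in reference replicase domains (NOT the deposited NDiV
; sequences, which require network access): random amino-acid sequences
; drawn i.i.d. from the WAG equilibrium frequencies with a fixed seed
; (20140520). span= gives each domain's 0-based half-open coordinates in
; the default synthetic pp1ab. Replace with a real reference FASTA of the
; same format to analyse real genomes.
>3CLpro span=2000-2250 synthetic=true
QGAKPYSCSDAASGLVIPPNMKTYGRKVGALELENRDAPGGTQHSGEETPTNNMGDVGDMDAFETGQVKG
CELMGGPLAYEEAVLDDVEVLNRLAHQVFELAAHTDGVSPKPERRVLFRHHHVQDLIVTAKLEGQEFGCT
SRNNPLFSIKTDNLAKRPSIFYRIVGFVAWGWLLMAEMKSRGTETPSRQLPTCMDVLFTRKEQANVLEKV
FIDLAPTVAADDGMWDVELQFILAIIMSTTTNRDPPMFVE
>RdRp span=3185-3585 synthetic=true
DDSQGSVKLDAMCKRGHVIGFLAAVRIQTALGYTRVKPTINLTPCASILGYITYAIDLLTMVVTWPELIL
VDRRVVAPAFLIAAYGDLVGLDGKIDIAWFVLPKFTTSCDPFDSTNIEQSNSQFHAIEMAGPAVQVKDQL
KSVLGCASRSTETTDNIAYDAVSRFFQSYVSWQAWEFCQRFRRCDCVRHVELVVTLYSMYPANLIILLGS
GEFRECICIKDPNWPESCLVKLSQPTNVKAQVADKYGKLVFAFYNAPLVRALEQNLGCTTETYNLNHSGE
YSDTCDSVGAWWVAASTPAELCAGYDSIVQLAEHTKPSCGSASAAKEMTNSDAALSLYARTQVATSGAHI
RRGNAECGSYGFSLFHNYAAAASTSATPKNLEAIEILFEASIGVDTTRTV
>ZnHel1 span=3685-3935 synthetic=true
ATAMKCPDAYGGNVSDPTRDRAPSLKQLYCRSGGEEIPSQKRSYDGGWFNTFSEQMLRAFDVQDRAWMGF
KHQDLTNIMRRFSGHLSVAAGSALMLSTVSVVETLRPRAELTIAAVSGETGRITQLESGGVGLKGRLATF
LGPMVKNFLLEIQRLAADFDIHASAFKTVNPQVSDVSIVSHYWRQGFKGQAGEEDFTGSDHTSTIDSVKS
VCISIALRNLEKVPAVALFGTLMLYTVARRGNAMVDSGSQ
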