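band_id,protein,peptide_matches,trend
band_2,Unknown,12,up
band_3,Unknown,33,up
band_3,Unknown,34,up
band_5,Not available,,down
band_6,Not available,,down
band_10,Not available,,down
band_14,Unknown,39,down
band_14,Unknown,36,down
band_22,RhoGAP (LbGAP),52,down
band_22,Unknown,21,down
band_22,Serpin (LbSPNm),17,down
band_22,RhoGAP (LbGAPy),11,down
band_23,Not analyzed,,down
band_27,RhoGAP (LbGAP2),20,down
band_27,Unknown,18,down
band_30,Unknown,19,up
band_35,Not available,,up
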