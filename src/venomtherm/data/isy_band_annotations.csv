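band_id,protein,peptide_matches,trend
band_1,Not analyzed,,up
band_10,Unknown,10,up
band_10,Unknown,10,up
band_11,Not available,,down
band_16,Unknown,16,down
band_18,Serpin (LbSPNy),81,down
band_19,Serpin (LbSPNy),81,up
band_21,Unknown,25,up
band_24,RhoGAP (LbGAPy4),24,up
band_28,Unknown,20,down
band_28,RhoGAP (LbGAPy2),17,down
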