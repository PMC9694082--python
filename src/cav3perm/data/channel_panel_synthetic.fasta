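>hCav3.1 synthetic encoding (not real sequence): classification-relevant residues only
SCTNLPAQSVQCGSGEGEDGDGDGTCAPCS
>hCav3.2 synthetic encoding (not real sequence): classification-relevant residues only
SCTNLPAQSVQCGSGEGEDGDGDGTCAPCS
>hCav3.3 synthetic encoding (not real sequence): classification-relevant residues only
SCTNLPAQSVQCGSGEGEDGDGDGTCAPCS
>Nav1.5 synthetic encoding (not real sequence): classification-relevant residues only
SCTNLPASSVQCGSGDGEQGKGAGTCAPGS
>Cav1.3 synthetic encoding (not real sequence): classification-relevant residues only
SGTNLPASSVQPGSGEGEDGEGEGTCAPGS
>Nav2-type synthetic encoding (not real sequence): classification-relevant residues only
SCTNLPASSVQCGSGDGESGEGAGTCAPGS
>LCav3-12a synthetic encoding (not real sequence): classification-relevant residues only
SCTCLPAKSVQCGSGEGEDGDGDGTCAPCS
>LCav3-12b synthetic encoding (not real sequence): classification-relevant residues only
SCTCLPAASCQCGSGEGEDGDGDGTCAPCS
>CeCav3-12a synthetic encoding (not real sequence): classification-relevant residues only
SCTNLPAKSVQCGSGEGEDGDGDGTCAPCS
>CeCav3-12b synthetic encoding (not real sequence): classification-relevant residues only
SCTCLPAMSVQCGSGEGEDGDGDGTCAPCS
>PaCav3a synthetic encoding (not real sequence): classification-relevant residues only
SCTNLPASSVQCGSGEGENGDGDGTCAPCS
>PaCav3b synthetic encoding (not real sequence): classification-relevant residues only
SCTNLPASSVQCGSGEGEDGDGDGTCAPGS
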