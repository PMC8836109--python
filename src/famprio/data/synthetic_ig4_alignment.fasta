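>human synthetic stand-in: Ig-like loop window around the audited V residue (column 11)
TAHHVLGSGEVWGSEPKDLT
>cow synthetic stand-in
TAHHVLGSGEVWGSEPKDMT
>rabbit synthetic stand-in
TSHHVLGSGEVWGSEPKDLT
>chicken synthetic stand-in
TSHHILGSGDVWGAEPRDLS
>cod synthetic stand-in
SSHHILGAGDVFGAEPRELS
>zebrafish synthetic stand-in
SSHQILGAGDVFGADPRELS
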