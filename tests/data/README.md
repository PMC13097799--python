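# Reference data

`lambda_phage.fasta` — the phage λ genome (GenBank J02459.1), used by one
benchmark test of the CCWGG dyad coordinates. The sequence is public
reference data and is not bundled; download the FASTA from GenBank and
place it here as `lambda_phage.fasta` to enable that check.
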