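# 19 x 10 MB autosomes + 10 MB X, recent inbreeding 10 generations back
g = 10
f_target = 0.18
theta_bg = 0.0027
epsilon = 0.0001
miss_rate = 0.05
seed = 1
x_length = 10000000
chrom chr1 = 10000000
chrom chr2 = 10000000
chrom chr3 = 10000000
chrom chr4 = 10000000
chrom chr5 = 10000000
chrom chr6 = 10000000
chrom chr7 = 10000000
chrom chr8 = 10000000
chrom chr9 = 10000000
chrom chr10 = 10000000
chrom chr11 = 10000000
chrom chr12 = 10000000
chrom chr13 = 10000000
chrom chr14 = 10000000
chrom chr15 = 10000000
chrom chr16 = 10000000
chrom chr17 = 10000000
chrom chr18 = 10000000
chrom chr19 = 10000000
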