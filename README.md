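# eccbarcodes

Systematic design of error-correcting DNA barcodes for multiplexed
sequencing, built from **quaternary LDPC codes** and **shortened binary BCH
codes**, together with the machinery to evaluate them — multiplexing
capacity, barcoding rate and error rates over a mismatch channel — and a
FASTQ demultiplexer that uses the codes' own decoders.

## Who this is for

Sequencing-core and library-prep developers who need barcode sets that are
larger and *more accurate* than exhaustively screened random barcodes, on
platforms dominated by substitution (mismatch) errors. Incomplete decoders
let the trade-off be chosen explicitly: undetected sample misassignments
(`p_u`) can be pushed to ~1e-9 at the cost of a small rate of detected
decode failures, i.e. read losses (`p_d`), with `p_e = p_u + p_d`.

## The methods in brief

* **LDPC barcodes.** A regular sparse parity-check matrix H (m×n over
  GF(4), column weight j = 3) defines a code with k = n − m informative
  quads and 4^k candidate barcodes of N = n bases. Edge positions are
  optimised with Progressive Edge Growth; the GF(4) values filling the
  support are drawn at random and candidate fills are ranked by the
  diversity score

  `D(H) = (μ_h,c − σ_h,c) · (μ_d,r − σ_d,r)`

  where the first factor summarises normalised pairwise Hamming distances
  between columns and the second pairwise cosine dissimilarities between
  rows; the best of a pool of 1000 fills is kept. Decoding is
  belief propagation over GF(4) (≤ 50 iterations) with quaternary
  symmetric channel priors; non-convergence is a *detected* failure.
* **Shortened BCH barcodes.** Binary BCH(n = 2^m − 1, k, t) codes are
  shortened by s bits to reach intermediate barcode lengths
  N = (n+1−s)/2 (s even) or (n−s)/2 (s odd), mapped two bits per base.
  A base mismatch induces 1 or 2 bit errors (2/3 vs 1/3), so at least
  b = ⌊t/2⌋ mismatches are always corrected. Decoding is Berlekamp–Massey
  plus Chien search, with miscorrections into shortened coordinates
  reported as failures.
* **Deployment pipeline.** Codewords pass through an S-random interleaver
  (breaking homopolymer runs), then a chemistry screen (max homopolymer
  run, G+C window). The survivors are the barcode set: capacity M,
  barcoding rate `B = log4(M)/N`.
* **Evaluation.** The quaternary symmetric channel mutates each base to any
  other with probability p_s/3. Error rates are estimated with a pooled
  Monte Carlo protocol (T samples × C trials, reference budget T = 100,
  C = 1e7) with 95% intervals and the zero-event bound
  `1 − exp(−2/CT)` = 2.00e-9 at the reference budget. For bounded-distance
  BCH decoding a closed-form tail gives exact p_e for cross-checking.

## Worked example

```bash
# 1. pick the best D-scoring (19, 4) quaternary LDPC code from 1000 fills
eccbarcodes design-ldpc --n 19 --k 4 --pool-size 1000 --seed 1 --out h19.alist
# (19, 4) code, D = 0.2376 (mu_hc=0.362 sigma_hc=0.044 mu_dr=0.884 sigma_dr=0.135) -> h19.alist

# 2. interleave, chemistry-screen and number the barcodes
eccbarcodes emit-barcodes --code h19.alist --seed 2 --out ldpc19
# M = 71 barcodes of N = 19 bases, B = 0.162 -> ldpc19.json

# 3. estimate error rates at a 1% per-base mismatch rate
eccbarcodes simulate --manifest ldpc19.json --ps 0.01 --t-samples 10 \
    --c-trials 100000 --seed 3 --report sim.tsv
# p_e = 1.000e-06 [0.000e+00, 3.000e-06]  p_u = 1.000e-06  p_d = 0.000e+00  (T=10, C=100000)

# 4. demultiplex reads (barcode at read start)
eccbarcodes demux --manifest ldpc19.json --reads run.fastq --ps 0.01 --out assign.tsv
```

Reading the numbers: of the 4^4 = 256 codewords, M = 71 survive the default
chemistry screen (max homopolymer run 2, GC ∈ [0.40, 0.60]), giving
B = log4(71)/19 = 0.162 informative quads per base. At p_s = 0.01 the
decoder misidentified 1 of the 1e6 simulated reads and lost none to
detected failures; longer LDPC barcodes (N ≥ 21) push p_u down to the
zero-event bound (~1e-9) at p_e ~ 1e-6.

A BCH equivalent: `eccbarcodes design-bch --n 63 --t 7 --s 15 --out bch.json`
prints `BCH(n=63, k=24, t=7, s=15): k'=9 bits, N=24 bases, b>=3 mismatches`.

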