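# asmqual

Reference-based quality assessment for de novo genome assemblies, with a
single consolidated score.

Assembly evaluation tools typically emit a dozen metrics (genome
fraction, N50 variants, misassembly counts, …) that can rank the same
set of assemblies in contradictory orders. `asmqual` instead scores each
scaffold individually against a trusted reference and consolidates the
assembly into one number in [0, 1], so assemblies — or successive builds
of the same genome — can be ranked directly.

## The score

Each scaffold *s* gets

```
Q(s) = L(s) · R(s) / (1 + P(s))
```

with **R(s)** the fraction of its non-gap bases that align to the
reference, **P(s)** = log₁₀₀(m_s − ε_s) when the misassembly count m_s
exceeds the calibrated artifact expectation ε_s by more than 1 (else 0),
and **L(s)** a length-scaling coefficient that is 1 for scaffolds at
least as long as the shortest reference chromosome θ_G and
−1/(log₁₀(l_s/θ_G) − 1) below it. Misassemblies are classified per
junction of the filtered alignment chain as relocation, translocation,
or inversion, with a user-adjustable relocation threshold (default
1000 bp). The assembly score is the geometric mean

```
Q(A) = (Δ_A · Ω_A · Π_A)^(1/3)
```

of the area under the cumulative quality-distribution curve (Δ_A), the
area under the cumulative genome-coverage curve (Ω_A), and the inverted
redundancy ratio Π_A = Φ_A/Σλ_i. See `docs/methods.md` for the full
model, assumptions and numerical choices.

## Worked example

Simulate an assembly of ~150 kb scaffolds from a toy 5 × 500 kb
reference with 10 misassemblies planted per scaffold, then score it from
its truth alignments:

```bash
asmqual simulate --design misassembly --mean-len 150000 --sd-len 1000 \
    --misassemblies 10 --seed 42 --out-dir demo
asmqual score --reference demo/reference.fa --assembly demo/assembly.fa \
    --paf demo/truth.paf --out-dir demo/out
```

which prints

```
wrote 20 scaffolds to demo
Q(A) = 0.4080  (Delta = 0.4250, Omega = 0.2514, Pi = 0.6359; 20 scaffolds)
```

Each scaffold carries exactly 10 misassemblies, so P(s) = log₁₀₀(10) =
0.5 everywhere, and at 150 kb against θ_G = 500 kb the length scaling is
≈ 0.66 — per-scaffold qualities land near 0.44 (see
`demo/out/scaffolds.tsv`):

```
query_id    l_s     R    m_s  epsilon_s  P    L       Q       assigned_chrom ...
scf_00000   150879  1.0  10   0.0        0.5  0.6577  0.4385  chr3
scf_00001   148960  1.0  10   0.0        0.5  0.6554  0.4369  chr5
```

The planted translocations and relocations also scatter scaffold
segments across the genome, which lowers the coverage curve (Ω) and
creates redundant placements (Π < 1): the consolidated score of 0.41
reflects all three defects at once. Scoring a perfect tiling of the
reference instead yields Q(A) = 1.0 exactly. `demo/out/` also contains
the two cumulative curves as CSV, a ten-bin quality histogram, and a
per-junction misassembly event table.

For real data: run `asmqual calibrate --reference ref.fa --out cal.tsv`
once per reference to fit the per-chromosome artifact model, map your
assembly (`minimap2 -x asm5 ref.fa asm.fa > aln.paf`), then
`asmqual score ... --paf aln.paf --calibration cal.tsv`.

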