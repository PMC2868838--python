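# coevomech

Connect sequence coevolution to coarse-grained protein mechanics.

Alignments of a protein family carry a statistical signature of coevolution:
pairs of positions whose amino-acid distributions are correlated. Sequence
statistics alone, however, say nothing about *why* two positions coevolve.
`coevomech` annotates that signal mechanically: it builds a sequence-specific
elastic network model of the protein, perturbs the interactions that
coevolving pairs form, and measures how much each perturbation changes the
molecule's equilibrium dynamics.

## The model

**Coevolution.** For alignment columns *i*, *j* with symbol frequencies
*p<sub>i</sub>(x)*, *p<sub>j</sub>(y)* and joint frequencies
*p<sub>ij</sub>(x, y)* over the 20 amino acids + gap + nonstandard marker,
the mutual information (bits)

```
MI_ij = Σ_{x,y} p_ij(x,y) · log2[ p_ij(x,y) / (p_i(x) p_j(y)) ]
```

measures the statistical dependence between the two positions. A shuffle
null model (independent within-column permutations) estimates the
finite-sample bias of the plug-in estimator.

**Mechanics.** Each residue is a bead at its Cα position. Sequence
neighbours (i, i+1) within a chain are joined by springs of strength α
(default 82); every other pair within 13 Å (squared cutoff 169 Å²) carries a
sequence-specific spring κ_ij taken from 20×20 amino-acid contact-energy
tables (Miyazawa–Jernigan magnitudes intra-chain; a Keskin-style table
inter-chain). The Hessian **H** of this harmonic potential at the native
state yields the covariance matrix through the Moore–Penrose pseudo-inverse
skipping the six rigid-body modes,

```
M = Σ_{k>6} λ_k⁻¹ v_k v_kᵀ ,         B_i = (8π²/3) · tr M_ii ,
```

with B<sub>i</sub> the isotropic B-factor of residue *i*.

**Perturbation scoring.** Breaking one non-covalent contact (or mutating one
residue) gives a perturbed covariance **M**′; the Frobenius norm
*f* = ‖**M** − **M**′‖<sub>F</sub> scores the mechanical impact. Plotting MI
against *f* for the top-MI contacts separates four classes of pairs
(high/low coevolution × high/low mechanical importance), assigned by
proximity to the corners of the normalized MI–f plane (45°, 135°, 225°,
315°). Pairs near 45° — strong coevolution *and* strong mechanical impact —
are candidates for functionally key interactions.

**Thermodynamics (SCPCP).** The self-consistent pair contact probability
extension weights each non-covalent spring by an occupancy probability
computed self-consistently from the model's own thermal fluctuations. The
feedback (open contacts soften the network, softer networks open more
contacts) produces a cooperative, temperature-driven loss of native
contacts — a finite-size analogue of unfolding.

## Worked example

Everything below runs on synthetic fixtures generated by the package itself
(a random 15-residue globule and a 500-sequence alignment with a planted
perfectly covarying column pair (2, 5)):

```
coevomech fixtures --topology globule --n 15 --seed 3 --out demo.pdb
coevomech fixtures-aln -L 15 -S 500 --couple 2,5:1.0 --seed 7 --out demo.fasta
coevomech simc --pdb demo.pdb --aln demo.fasta --top 5 --workers 2 --out results.tsv
```

`results.tsv`:

```
i	j	MI	fnorm	quadrant
2	5	4.285490	0.088414	315
1	13	0.714331	0.064956	225
0	9	0.702769	0.169292	135
7	9	0.669735	0.020395	225
0	7	0.660444	0.116240	135
```

The planted pair (2, 5) tops the MI ranking at 4.29 bits (the column entropy
— the maximum possible for a deterministic coupling); background pairs sit
near the finite-sample bias level (~0.7 bits at S=500). Its quadrant label
315° reads "strong coevolution, modest mechanical impact": breaking contact
(0, 9) instead perturbs the covariance twice as strongly (f = 0.169).

A stability-decreasing temperature scan shows the cooperative unfolding of
the same globule:

```
coevomech scpcp --pdb demo.pdb --beta-scan "2.0:0.4:-0.2" --out scan.tsv
```

```
beta	mean_contact_prob	iterations	converged	disconnected
2.000000	0.989769	19	True	False
1.400000	0.952946	23	True	False
1.000000	0.836543	37	True	False
0.800000	0.601104	102	True	False
0.600000	0.000000	35	True	True
```

The mean contact probability (the order parameter) falls from ≈0.99 to 0
between β = 0.8 and β = 0.6 — the sharp, sigmoidal drop expected of a
finite-size folding/unfolding transition; the `disconnected` flag marks the
unfolded states. The `iterations` column peaks near the transition, where
the fixed point is softest.

The same pipelines are available as library calls (`read_pdb`,
`build_contacts`, `solve`, `mutual_information`, `run_break_protocol`,
`scpcp_solve`, …); see `docs/methods.md` for the model details and the
numerical choices.

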