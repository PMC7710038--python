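# shiftscape

Forward-in-time Gillespie simulation of the substitution process along a
rooted phylogeny when the **single-position fitness landscape itself changes
over time** — stochastically, at fixed epochs, or at user-chosen branch
coordinates.

Most sequence simulators evolve sites under a fixed substitution model.  But
the fitness landscape of a site — the vector of fitness values of its
possible alleles — drifts in reality, whether through environmental change,
host–pathogen arms races, or epistasis with other evolving sites.
`shiftscape` is for researchers who want to generate sequence alignments
(with full ancestral states and a log of every landscape change) under such
dynamics, on a phylogeny of arbitrary shape, to study their footprint on the
substitution process.

## The model

A landscape is a vector of population-size-scaled additive fitnesses,
`F_i = 2N f_i`, one entry per allele of an arbitrary alphabet.  With a
matrix `M` of relative mutation rates (all ones by default), the
instantaneous substitution rate from allele `i` to `j` is the classical
mutation–selection (Halpern–Bruno) form

    q_ij = M_ij (F_j − F_i) / (1 − exp(F_i − F_j)),   i ≠ j,

with `q_ij = M_ij` when `F_i = F_j` and `q_ii = −Σ_{j≠i} q_ij`.  The
stationary distribution solves `πQ = 0`; for all-ones `M` it is the
Boltzmann/softmax form `π_i = exp(F_i)/Σ_j exp(F_j)`.  By default `Q` is
normalized by its expected rate `−Σ_i π_i q_ii` so that one substitution is
expected per position per unit branch length; a flat scaling by `|A|−1`
(neutral landscapes tick at rate 1, selection slows the clock) and the raw
matrix are also available.

Evolution along each branch is simulated exactly (Gillespie): exponential
waiting times in the summed exit rates of all positions, plus — in the
stochastic regime — a landscape-change "extra site" with user rate λ.
Deterministic change schedules (evenly spaced epochs, or explicit branch
coordinates) race against the substitution clock; every change recomputes
`Q` and `π` and the process continues under the new landscape.  New
landscapes are produced by resampling, permutation, explicit user vectors,
or by increasing/decreasing the fitness of the currently resident allele.
At an epoch shared by several lineages the replacement landscape can be
drawn once for all of them or independently per lineage.

## Worked example

A 4-leaf tree with total branch length 8, one landscape over 30 positions,
Poisson landscape changes at rate 1 per unit branch length, each change
shuffling the fitness vector:

```
$ cat run.ini
[run]
tree = simple.nwk            ; ((A:1.5,B:1.5)E:1,(C:1.5,D:1.5)F:1)G;
alphabet = ACGT
seed = 42
output_dir = out
write_change_log = true
write_internal_nodes = true

[landscape]
length = 30
instances = 1
init = lognormal mu=0 sigma=0.5
change_rule = permute
timing = stochastic rate=1

$ shiftscape --config run.ini
INFO 1 instance(s) complete; mean landscape changes per instance: 4.000
leaves_fasta: out/sequences_leaves.fasta
all_nodes_fasta: out/sequences_all_nodes.fasta
change_log: out/change_log.tsv
manifest: out/manifest.tsv
```

Four changes is in line with the expectation λ × (total branch length) = 8
for a single draw.  The change log records, for every change, the lineage,
its global time (distance from the root), the offset from the branch start
and the new fitness vector:

```
instance  group      landscape_id  branch  global_time   offset        F_A        F_C       F_G       F_T
0         landscape  1             E       0.6152544595  0.6152544595  0.5945253  1.600446  1.164578  1.455320
0         landscape  4             C       1.689328827   0.6893288266  1.164578   1.600446  0.5945253 1.455320
...
```

The FASTA files contain the simulated sequence at every leaf (and,
optionally, every internal node), e.g. `>G ATTTAGGTGTGCGATGTGTTTAGAATTTCG`
for the root.  The same machinery is available as a library:
`load_inputs`, `run_parallel` and `write_outputs` in `shiftscape.io_cli`,
or `run_simulation` directly for a single landscape instance.

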