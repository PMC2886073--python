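# phylodiv

Partition the diversity of a quantitative trait among the nodes of a
phylogeny — and compare **intra**-specific with **inter**-specific
variability by treating within-species replicate measurements as *virtual
sister-taxa*.

Comparative datasets (the motivating case is dispersal metrics measured in
multiple populations of European butterflies) often carry several values per
species. The usual practice of averaging them assumes within-species
variation is negligible relative to differences among species. `phylodiv`
tests that assumption directly, for ecologists and evolutionary biologists
working with branch-length-free classification trees.

## The method

Trait diversity is measured by Rao's quadratic entropy, which for a single
quantitative trait with dissimilarity `d_ij = (x_i − x_j)² / 2` equals the
(divisor-*n*) variance of the tip values. Values are Box-Cox transformed and
standardized so the total diversity is 1. Each internal node *k* of the
rooted topology receives a contribution

    ν_k = p_k · d_k

where `p_k` is the proportion of tips descending from *k* and `d_k` is the
diversity *among the child clades* of *k* (the between-group term of the law
of total variance). The contributions telescope: `Σ_k ν_k` equals the total
diversity exactly.

When a species has several population-level measurements, its tip is
replaced by an **artificial node** whose children are one virtual tip per
population. On this *enlarged* tree:

* **S_c** = `Σ ν_k` over artificial nodes — the proportion of trait variance
  that is intra-specific. The *trait conservation test* permutes all tip
  values jointly (mixing intra- and inter-specific variation) and asks
  whether the observed S_c is unusually **low** (left-tailed).
* **S_3** = `Σ_k (ν_k / total) · rank_k`, with internal nodes ranked 0 (most
  distant from the tips of the reference tree) to 1 (most tipward) —
  a *skewness-to-root* statistic, tested two-sided against the same
  permutation null.
* **Abouheif's C_mean** — phylogenetic signal in species means on the pruned
  species tree: Moran's *I* with proximities `a_ij = Π 1/DDC` over the
  internal nodes on the path between tips *i* and *j* (DDC = number of
  direct descendants), tested upper-tailed.

P-values use the `(r+1)/(N+1)` estimator (default N = 1000 permutations) and
are Hochberg-corrected across metrics within each statistic family.

## Worked example

```python
import phylodiv as pv

tree = pv.parse_newick("((A,B),(C,D));")
z, _ = pv.standardize([0.0, 2.0, 4.0, 6.0])
dec = pv.decompose_diversity(tree, dict(zip("ABCD", z)))
print(dec.to_frame().to_string(index=False))
```

```
 node_id clade_tips   p   d  nu  is_artificial
       0    A,B,C,D 1.0 0.8 0.8          False
       1        A,B 0.5 0.2 0.1          False
       4        C,D 0.5 0.2 0.1          False
```

The root separates {0, 2} from {4, 6} and carries 80% of the trait variance;
each cherry holds 10%. On the same tree `pv.abouheif_cmean(tree, ...)` gives
C_mean = 2/15 ≈ 0.133.

With replicated species (see `examples/02_conservation_test.py`, which
simulates 18 species, 8 of them with replicate populations, at a designed
within-species variance share of 0.15):

```
designed within-species share: 0.150
observed S_c:                  0.122
left-tailed p (999 permutations): 0.0010
```

The trait is conserved within species: populations of a species differ far
less than random pairs of tips would.

The `examples/` directory has one short script per capability; the
`phylodiv` command exposes the same pipeline from the shell
(`phylodiv run --tree tree.nwk --traits traits.csv --seed 1 --out results/`,
plus `decompose`, `test-conservation`, `test-skewness`, `signal`, `adjust`
and `simulate` subcommands).

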