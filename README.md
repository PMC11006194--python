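# moranamp

Moran Birth-death and death-Birth dynamics on weighted, undirected graphs:
exact and simulated fixation probabilities, closed-form baselines, node
temperature and first-step bias, amplifier classification, and composite
graph constructions that amplify selection under **both** update rules.

## The problem

A population of `N` asexually reproducing individuals lives on a connected
weighted graph `G_N = (V, E)`: nodes are sites, edge weights `w(u, v)`
are interaction strengths that bias offspring migration. A single mutant
with relative fitness `r` (residents have fitness 1) appears at a uniformly
random node; eventually it either fixates or goes extinct. The Moran
process comes in two versions:

- **Birth-death (Bd)** — `u` reproduces with probability `f(u)/F`
  (fitness-proportional), and the offspring replaces a neighbour `v` with
  probability `w(u,v)/deg(u)`;
- **death-Birth (dB)** — `v` dies with probability `1/N`, and the vacancy
  is filled by neighbour `u` with probability
  `f(u)·w(u,v) / Σ_u' f(u')·w(u',v)`.

On the complete graph `K_N` (the well-mixed baseline),

```
ρ_Bd(K_N) = (1 − 1/r) / (1 − r⁻ᴺ)
ρ_dB(K_N) = ((N−1)/N) · (1 − 1/r) / (1 − r⁻⁽ᴺ⁻¹⁾)
```

A graph whose uniform-initialization fixation probability exceeds this
baseline is an **amplifier of selection** under that update rule;
falling below makes it a suppressor. Classic amplifiers are
rule-specific: the star amplifies under Bd but suppresses under dB, the
(weighted) fan does the reverse. This package implements the machinery to
compute and classify fixation probabilities under both rules — full
`2^N`-state linear solves, exact symmetry-lumped chains for the structured
families, seeded Monte Carlo — together with:

- the **temperature** `T(u) = Σ_v w(v,u)/deg(v)` and the first-step
  survival probability `γ` (for Bd, `γ = r/(r + T(u))`), plus numerical
  sweeps of two impossibility results: at `r = 1` no starting node beats
  `1/N` under both rules at once, and no node improves `γ` under both
  rules at once;
- the composite graph `A_N` (`make_amplifier_AN`): a Bd-amplifying chunk
  (hub of `a` nodes plus `b` two-node blades) and a dB-amplifying fan of
  `f` nodes joined by a single edge of weight `t⁻³`, whose weight
  asymmetry reverses the direction of offspring flow across the connecting
  edge between the two update rules — the mechanism that lets large
  instances amplify under both;
- a coarse **chunk-coupling model** of `A_N` (four states: all-resident,
  either chunk fixed, all-mutant) that reproduces the exact lumped
  solution of the 26-node instance to ~1e−5 relative.

## Worked example

```python
import moranamp as ma

S11 = ma.make_star(11)
for kind in ("Bd", "dB"):
    v = ma.classify(S11, ma.ProcessSpec(kind, 1.05))
    print(f"{kind}: rho(S11) = {v.rho_graph:.6f}  rho(K11) = {v.rho_baseline:.6f}  "
          f"ratio = {v.ratio:.3f}  -> {v.verdict}")
print("T(center) =", ma.temperature(S11, "center"), " T(leaf) =", ma.temperature(S11, "leaf-0"))
```

prints

```
Bd: rho(S11) = 0.131760  rho(K11) = 0.114656  ratio = 1.149  -> amplifier
dB: rho(S11) = 0.094603  rho(K11) = 0.112125  ratio = 0.844  -> suppressor
T(center) = 10.0  T(leaf) = 0.1
```

The star on 11 nodes raises a 5%-advantage mutant's fixation probability
by 15% over the well-mixed population under Birth-death updating, while
*lowering* it by 16% under death-Birth updating. The hot center
(`T = N − 1`) is replaced constantly, the cold leaves rarely — good for a
mutant seeded on a leaf under Bd, bad under dB where high-degree nodes win
vacancies.

The same machinery from a shell:

```sh
moranamp generate star --n 11 --out star.tsv
moranamp classify --graph star.tsv --process bd --r 1.05
moranamp scan --graph star.tsv --process db --r-grid 1.01:1.1:0.01 --out curve.csv
```

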