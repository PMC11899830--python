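# conntopo

Connection-based topological indices of molecular graphs, with the QSPR
statistical battery used to rank them against experimental physicochemical
data.

## What it does

In a hydrogen-suppressed molecular graph (heavy atoms = vertices, bonds =
edges), the **connection number** con(v) of an atom is the number of atoms at
shortest-path distance exactly 2.  A family of sixteen topological
descriptors is built on con: the first and second Zagreb connection indices

    Mc1 = Σ_{ij∈E} (con_i + con_j),        Mc2 = Σ_{ij∈E} con_i·con_j,

their multiplicative versions Πc1/Πc2, the (general) Randić connection index
Rcβ = Σ (con_i·con_j)^β, the (general) sum-connectivity connection index
SCcβ = Σ (con_i + con_j)^β, and the atom-bond-connectivity, augmented-Zagreb,
geometric–arithmetic, arithmetic–geometric, reduced (reciprocal) Randić,
Sombor and modified-first-Zagreb connection indices.

For quantitative structure–property work the package provides a screening
battery: the multiple linear correlation ρ = √R² of each descriptor regressed
(OLS with intercept) on two experimental properties — normal boiling point
ρbp and standard heat of formation Δhf — descriptor ranking, full OLS models
with t-based 95% confidence intervals, leave-one-out cross-validation RMSEs,
and univariate polynomial (degree 1–3) structure–property models with R²
grids.

The 22 lower benzenoid hydrocarbons (benzene … coronene) ship as validated
edge-list fixtures together with their experimental ρbp/Δhf values, and a
25-compound coumarin-drug property table (11 physicochemical properties) is
included for user-supplied structures.  Intended users: mathematical
chemists evaluating descriptor families, and anyone needing exact,
reproducible connection-index values.

## Worked example

```python
from conntopo import load_bh22, descriptor_table, screening_report, fit_mlr

fs = load_bh22(anthanthrene="as-published")   # the reference dataset variant
desc = descriptor_table(fs.graphs)            # 22 compounds x 21 descriptors
print(desc.loc[["Benzene", "Naphthalene", "Pyrene"],
               ["MC1", "MC2", "PC1", "SCC", "SCC_B-1"]])

rep = screening_report(desc, fs.properties)   # MLC screening + ranking + MLR
print(rep["ranking"].round(4))
```

prints

```
             MC1  MC2                PC1       SCC   SCC_B-1
compound
Benzene       24   24               4096  3.000000  1.500000
Naphthalene   64   96          192080000  4.654266  1.996429
Pyrene       140  270  15564962700000000  7.182653  2.759524

         descriptor     rho
position
1           SCC_B-1  0.9336
2                RC  0.9335
3               SCC  0.9318
4              ABCC  0.9310
5               GAC  0.9279
```

Every value is recomputed from the packaged structures: benzene's six edges
each join atoms with con = 2, so Mc1 = 6·(2+2) = 24 and Πc1 = 4⁶ = 4096
(exact integers; Πc1 on pyrene is already ~1.6·10¹⁶ and is kept exact).  The
general sum-connectivity index at β = −1 tops the screening with ρ = 0.9336:
its values correlate best with the two experimental properties across the 22
compounds.  The full model behind that number:

```python
fit = fit_mlr(desc["SCC_B-1"], [fs.properties["bp"], fs.properties["hf"]],
              term_names=("bp", "hf"))
print(fit.summary())
```

```
OLS fit: n=22, p=2
  r^2 = 0.8716   r = 0.9336
  s = 0.2644   F = 64.4647
     intercept = +0.855059 +/- 0.470199 (95% CI)
            bp = +0.00180828 +/- 0.00326978 (95% CI)
            hf = +0.00562234 +/- 0.005537 (95% CI)
```

The same pipeline is scriptable from the shell:

```bash
conntopo fixtures --set bh22 --anthanthrene as-published --out work/bh22
conntopo compute  --input work/bh22 --out work/desc
conntopo qspr     --descriptors work/desc/descriptors.csv \
                  --properties work/bh22/bh22_properties.csv \
                  --mlc-targets bp,hf --top-k 5 --out work/report
```

Note the two anthanthrene variants: the packaged default is the correct
C22H12 skeleton, while `as-published` substitutes the graph the original
reference dataset demonstrably used (see `docs/methods.md` for the full
story of this and the other reference-data discrepancies the package
documents).

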