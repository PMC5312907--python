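# nanodisp

QSPR modelling of single-walled carbon-nanotube (SWCNT) dispersibility in
organic solvents.

Finding solvents that disperse SWCNTs well is expensive to do empirically.
This package models the maximum stable dispersed concentration `C` (mg/mL)
of SWCNTs in a solvent directly from the solvent's molecular structure: the
endpoint `LogC = log10 C` is regressed on a handful of molecular
descriptors, so dispersibility can be screened for new solvents before any
lab work.  It is aimed at cheminformatics practitioners who want a small,
fully testable reference implementation of the classic GA-MLRA workflow —
descriptor computation, genetic-algorithm subset selection, ordinary least
squares with leave-one-out statistics, and external r_m² validation —
together with the 29-solvent dispersibility dataset it was built around.

## The model

The core is multiple linear regression with subset selection:

    LogC = b0 + b1·d1 + … + bp·dp,    p ≤ 5

where the `d_i` are molecular descriptors computed on the hydrogen-depleted
molecular graph (plus one supplied quantum-chemical column):

| descriptor | meaning |
| --- | --- |
| `SRW09` | self-returning walk count of order 9, trace(A⁹); probes five-membered rings |
| `Ram`   | ramification (branching) index, Σ max(0, deg−2) |
| `X0Av`  | average zeroth-order valence connectivity, mean of δᵥ^(−1/2) (Kier–Hall δᵥ) |
| `piPC05`| multiple path count of order 5: Σ over simple 5-edge paths of Π bond orders (Kekulé) |
| `ATS6m` | Broto–Moreau autocorrelation, lag 6, atomic-mass weighted |
| `DipoleZ` | Z component of the dipole moment — always a supplied input |

Model quality is judged by `R²`, residual standard error `s`, the `F`
statistic, leave-one-out `PRESS`, `Q² = 1 − PRESS/TSS`, `SPRESS`, `SDEP`,
and on the external test set by `R²_test` and Roy's
`r_m² = r²(1 − √(r² − r0²))` metrics (average > 0.5 and |Δ| < 0.2 to
accept).  Subset search uses a seeded genetic algorithm with an exhaustive
enumeration oracle for small pools.

## Worked example

```python
from nanodisp import DispersibilityMLR, corpus

df = corpus.study_frame()          # descriptors + LogC + split, 29 solvents
train = df[df.split == "train"]    # the 22 training compounds

res = DispersibilityMLR.from_dataframe(train, "LogC", ["SRW09"]).fit()
print(res.summary())
```

prints

```
LogC = +0.0020 (±0.0008) SRW09 -2.1553 (±0.3626)
n = 22, R² = 0.547, s = 0.628, F = 24.158, p = 8.36e-05
LOO: PRESS = 9.567, Q² = 0.451, SPRESS = 0.692, SDEP = 0.675 (df convention: n-1)
```

Every unit increase in the 9th-order self-returning walk count (i.e. more
five-membered-ring environment, as in the pyrrolidinone solvents) raises
the predicted log-dispersibility by 0.0020; the model explains 55% of the
training variance and retains Q² = 0.45 under leave-one-out, so the
association is real but a single topological count is not enough for
screening — the larger subsets found by `ga_select` improve on it.

The GA/validation layer works the same way from the shell:

```sh
nanodisp pipeline --preset packaged --seed 1 --out artifacts/
nanodisp reproduce-paper
```

`reproduce-paper` refits all published descriptor subsets on the packaged
data, prints a comparison table of every statistic, and reports —
separately from the hard checks — the packaged reference values that are
internally inconsistent and therefore not reproducible (see
`docs/methods.md`).

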