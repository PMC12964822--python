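# pedinbreed

Pedigree-based inbreeding coefficients (F) for large livestock
populations, built around a **modified indirect method**: one sparse row
of the Cholesky factor `L` is computed per sire (descending
longest-ancestral-path traversal) and shared across all of the sire's
half-sib progeny, while a flagged recursive forward substitution touches
only the mates' ancestors and resets its workspace sparsely. The package
also ships the reference algorithms it cross-validates against, so every
answer can be checked by an independent route:

| tag       | algorithm                                                |
|-----------|----------------------------------------------------------|
| `mi`      | modified indirect method (LAP-block parallel)            |
| `i`       | original indirect method over a reduced pedigree         |
| `si`      | per-animal descending-LAP traversal                      |
| `ml`      | per-animal descending-identification-number traversal    |
| `rec`     | memoized recursive kinship                               |
| `tabular` | dense relationship-matrix oracle (small pedigrees only)  |

Unknown parents are modeled with per-birth-year-bin **metafounders**
(configurable self-relationship `gamma`; `gamma = 0` reproduces the
classical unrelated-founder F exactly). Input cleaning implements
birth-year imputation (oldest progeny minus a generation interval) and
severing of parent links born in the same year as or after their progeny.
A pedigree simulator generates factorial-mating growth designs with
half-sib family sizes 1000 / 200 / 4 whose census is checkable in closed
form.

## CLI

```sh
# clean a pedigree file (animal sire dam [birth_year]; "0" = unknown)
# and compute F with the modified indirect method on 4 threads
pedinbreed compute ped.txt -o f.tsv -a mi --workers 4 --report run.json

# cross-validate several algorithms at 1e-10
pedinbreed compare ped.txt -a mi,i,si,ml,rec

# generate a synthetic pedigree (family size 1000, 35 generations)
pedinbreed simulate --family-size 1000 -g 35 -s 1 -o sim.txt --census-json census.json
```

Exit codes: 0 success, 1 comparison failure, 2 input/usage error.

## Library

```python
import pedinbreed as pb

raw = pb.read_pedigree("ped.txt")
raw, _ = pb.impute_birth_years(raw)
raw, _ = pb.fix_birth_order_errors(raw)
raw = pb.assign_metafounders(raw, pb.MetafounderPolicy(gamma_default=0.0))
ped = pb.build_pedigree(raw)          # renumbered, LAP-sorted
res = pb.inbreeding_mi(ped, workers=8)
pb.write_results(ped, res, "f.tsv")
```

## Layout

- `src/pedinbreed/pedio.py` — parsing, cleaning, metafounders, LAP sort, output
- `src/pedinbreed/kincore.py` — dense oracles, L-rows, classical algorithms
- `src/pedinbreed/indirect.py` — original and modified indirect solvers
- `src/pedinbreed/pedsim.py` — simulation designs and random test pedigrees
- `src/pedinbreed/cli.py` — `compute` / `compare` / `simulate`
- `tests/` — unit, property and acceptance suites
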