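# gapdesign

Iterative inverse design of small organic molecules with a target
HOMO–LUMO gap (HLG), for computational chemists prototyping
surrogate-in-the-loop molecular discovery workflows.

Searching chemical space for molecules with a desired electronic property is
limited by the cost of the quantum-chemistry oracle that evaluates each
candidate. `gapdesign` implements a closed design loop that spends the oracle
budget where it matters:

1. an **oracle** labels molecules with a gap in eV (a deterministic toy gap
   function ships for desk-scale experiments; an adapter contract accepts any
   external electronic-structure backend);
2. a **graph-network surrogate** — a principal-neighborhood-aggregation (PNA)
   message-passing regressor over 11-dimensional node features and
   one-hot bond features — learns structure → gap from the labeled database;
3. a **masked-SMILES generator** mutates the current population by masking a
   short token span of each SMILES and refilling it from a
   frequency-weighted vocabulary, producing novel valid molecules;
4. **data-selection rules** decide what enters the next training set:
   * *rule 1a* — admit only molecules whose surrogate error exceeds the
     maximum train/validation/test error of the current surrogate,
   * *rule 1b* — keep only molecules unique in the integrated database
     (by canonical SMILES),
   * *rule 2* — restrict training additions to < 20 heavy atoms; larger
     molecules become monitoring test data;
5. each generation is **rank-selected** by gap value toward the objective
   (minimize by default, maximize supported), integrated into the database,
   and the surrogate is retrained from scratch.

The loop's two measurable claims, both reproduced by the test suite on
synthetic populations: the per-generation mean gap decreases monotonically
under minimization, and the error-driven data admission keeps the retrained
surrogate's accuracy flat across generations while a surrogate frozen at
generation 0 drifts.

## Toy oracle

With `U` the heavy atoms that are aromatic or touch a double/triple bond,
`Cmax` the largest connected component of the subgraph induced by `U`, and
`f_F` the fluorine fraction of heavy atoms:

```
gap = g_min + (g0 − g_min)·exp(−α·Cmax) + δ·f_F
```

(defaults `g0 = 14 eV`, `g_min = 0.5 eV`, `α = 0.25`, `δ = 8 eV`). Saturated
molecules sit near 14 eV, benzene at ≈ 3.51 eV, extended conjugation
approaches 0.5 eV, and CF₄ reaches 20.4 eV — the same qualitative
structure–property axes (conjugation lowers the gap; saturation and
fluorination raise it) that govern semi-empirical gap calculations.

## Worked example

```python
import numpy as np
import gapdesign as gd
from gapdesign.surrogate import SurrogateConfig

seeds = gd.make_seed_population(gd.FixtureConfig(n_molecules=300, seed=42))
gaps = [gd.toy_gap(gd.parse_smiles(s)) for s in seeds]
print(f"seed population: {len(seeds)} molecules, "
      f"mean gap {np.mean(gaps):.2f} eV (min {min(gaps):.2f}, max {max(gaps):.2f})")

cfg = gd.WorkflowConfig(
    n_iterations=3, generation_target=300, oversample=3.0,
    surrogate=SurrogateConfig.desk(epochs=120), master_seed=42,
)
result = gd.run_workflow(cfg, seeds)
for rep in result.reports:
    print(f"iteration {rep.iteration}: mean gap {rep.mean_gap_generation:.2f} eV, "
          f"admitted {rep.n_new_train} train / {rep.n_new_test} test "
          f"(rule-1a threshold {rep.threshold_used:.2f} eV)")

audit = gd.frozen_surrogate_audit(result.surrogate0, result.final_surrogate, result.db)
print(audit.round(3).to_string(index=False))
```

prints

```
seed population: 300 molecules, mean gap 9.63 eV (min 2.33, max 18.00)
iteration 1: mean gap 6.43 eV, admitted 72 train / 227 test (rule-1a threshold 0.85 eV)
iteration 2: mean gap 5.39 eV, admitted 1 train / 299 test (rule-1a threshold 2.48 eV)
iteration 3: mean gap 5.05 eV, admitted 8 train / 291 test (rule-1a threshold 1.81 eV)
 generation  n_molecules  mae_frozen_eV  mae_latest_eV
          0          300          0.092          0.214
          1          299          0.553          0.431
          2          300          0.917          0.614
          3          299          1.117          0.675
```

Read it as: rank selection drives the mean gap of each accepted generation
down from 9.63 eV (seeds) to 5.05 eV in three iterations; the surrogate
frozen at generation 0 degrades from 0.09 to 1.12 eV MAE as the population
moves away from its training distribution, while the final retrained
surrogate stays at or below 0.68 eV everywhere.

The same operations are scriptable from the shell:

```bash
gapdesign fixtures --n 300 --seed 42 --out seeds.smi --gaps-out gaps.csv
gapdesign run --seeds seeds.smi --iterations 3 --generation-target 300 \
              --master-seed 42 --outdir run/
gapdesign analyze --db run/population.csv --outdir analysis/
```

`analyze` writes per-molecule descriptors (H/C ratio, aromaticity ratio,
double-bond equivalents, heavy-atom count), per-generation summaries, and a
two-dimensional principal-component map of 2048-bit extended-connectivity
fingerprints.

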