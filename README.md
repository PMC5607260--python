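# ligandtree

Predicting ligand-dependent tumor-cell proliferation from simulated
signaling features.

About half of cancer cell lines proliferate when a growth factor — EGF,
heregulin (HRG), HGF or IGF-1 — is added, yet the surface level of the
cognate receptor alone is a poor predictor of who responds.  `ligandtree`
implements a two-stage pipeline for this problem:

1. **A mechanistic ODE model** of ErbB-family, Met and IGF-1R signaling:
   receptors bind ligand, form ten homo- and heterodimers (the kinase-dead
   ErbB3 homodimer forms but cannot signal), traffic through
   internalization/recycling/degradation, and drive the MAPK (MEK→ERK) and
   PI3K (AKT) cascades, which converge on S6K1 and S6 under negative
   feedback.  All kinetic rates are shared between cell lines; the *only*
   line-specific inputs are the five receptor surface counts, and the
   ligand-free basal state is solved analytically from steady-state
   constraints so that measured expression is the basal level.

2. **Bagged decision trees** that map simulated signaling features — the
   area under the curve x(t) integrated over the 4-h stimulation,
   AUC = ∫₀²⁴⁰ x(t) dt, of each signaling dimer plus pAKT/pERK/pS6 (12
   features), together with KRAS/PIK3CA mutation flags — to the observed
   proliferation phenotype.  Splits maximize a signal-to-noise gain
   Σ_c S_c²/n_c − S²/n (S = responders in a node of size n); evaluation
   leaves whole cell lines out over 500 random train/test splits and is
   compared against a 50%-accuracy random control.

A responder is a (line, ligand) pair whose 3-day viability exceeds its
control by >20% with exact Wilcoxon rank-sum p < 0.05 on quadruplicates.
The package ships a 58-line reference panel (receptor surface counts and
mutation annotations), synthetic-data generators with known ground truth
for every input the pipeline consumes (time courses, viability screens,
patient-style expression cohorts), maximum-likelihood calibration with
multi-start trust-region least squares, nested-model likelihood-ratio
testing with boundary correction, and a cohort application that tests
predicted responders for elevated ligand expression.

## Worked example

Simulate one reference line and run the synthetic pipeline end to end:

```python
import pandas as pd
from ligandtree import StimulusCondition
from ligandtree.io import fixture_contexts
from ligandtree.synth import GroundTruth, make_cell_lines, make_viability
from ligandtree.features import feature_table
from ligandtree.phenotype import call_table
from ligandtree.bdt import (LabeledFeatureSet, evaluate_splits,
                            compare_to_control, train_bagged)

truth = GroundTruth.default(seed=1)          # model + default kinetics
h322m = {c.name: c for c in fixture_contexts()}["H322M"]
traj = truth.model.simulate(h322m, StimulusCondition({"EGF": 5.0}))
print(traj.observable("pERK").max())         # 0.657 (peak at 15 min)

contexts = make_cell_lines(20, seed=1)       # synthetic 20-line panel
feats = feature_table(truth.model, contexts)
records, _ = make_viability(truth, contexts, seed=2)
calls = call_table(records, treatments=set(feats["ligand"]))
labels = pd.DataFrame([{"cell_line": c.cell_line, "ligand": c.treatment,
                        "responder": c.responder} for c in calls])
data = LabeledFeatureSet.from_tables(feats, labels)
ev = evaluate_splits(data, n_reps=200, seed=3, n_trees=30)
ctrl = evaluate_splits(data, n_reps=200, seed=3, control=True)
print(ev.mean_accuracy, ctrl.mean_accuracy)  # 0.874 vs 0.507
print(compare_to_control(ev, ctrl))          # 1.7e-34
```

For the H322M line, 5 nM EGF produces a phospho-ERK peak of 0.657 (active
fraction) at 15 min relaxing to 0.633 by 240 min.  On the synthetic panel
(51% responders under the planted rule with 10% label noise), the bagged
trees reach 0.874 ± 0.120 held-out accuracy over 200 cell-line splits
against a 0.507 random control (paired signed-rank p ≈ 2e-34), and the
feature importances rank `auc_pAKT` and `auc_pS6` on top — the planted
rule acts on pS6, and pAKT co-varies with it through the shared PI3K
drive.

The same stages are exposed on the command line:

```sh
ligandtree synth viability -n 20 --seed 1 -o viability.csv
ligandtree call-responders -i viability.csv -o calls.csv
ligandtree features --no-fixture -n 20 --seed 1 -o features.csv
ligandtree evaluate --features features.csv --calls calls.csv -o eval.csv
```

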