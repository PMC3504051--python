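# fragmind

Interpretable models of how chemists prioritize chemical fragments.

When medicinal chemists review a library of fragment-sized compounds
(MW ≤ 300) and pick the ones they would pursue, which molecular
properties actually drive those decisions — and do the chemists
themselves know? `fragmind` builds the statistical machinery to answer
that question from nothing but a binary selection matrix: interpretable
semi-naïve Bayesian (SNB) classifiers with forward feature-subset
selection, an orthogonal balanced random-forest validation, and a
consensus/awareness analysis suite (modified Tanimoto similarity,
consensus voting, the cultural consensus model, and exact binomial /
Fisher / paired-t comparisons).

Because real fragment-survey data are proprietary, the package ships a
first-class synthetic-data module: a scaffold-decoration generator for
a ~3,700-fragment library split into 8 batches with 227 deliberate
cross-batch duplicates, plus simulated "chemists" — rule-based selectors
with known ground-truth criteria and 5% label noise, size/polarity
strategy selectors including an XOR pattern, and random selectors. Every
analysis is validated by recovering what the simulated selectors were
built to do.

## The model

Each feature f — a (descriptor, bin) or (key, level) pair — receives a
Laplacian-corrected Bayesian score

```
s_f = ln( ((A_f + 1) / (T_f + 1/P)) / P )
```

where T_f counts training compounds with the feature, A_f those labelled
desirable, and P is the desirable-class prior. A compound's total score
is Σ s_f over its features; positive ⇒ desirable. The classifier is
*semi*-naïve: descriptors can be treated jointly as a composite key
(e.g. the ring-topology key `ring_bonds_aromatic_bonds_assemblies`, or
an on-the-fly atoms × polar-surface-area key), which lets the additive
model express feature interdependencies — including XOR patterns — that
independent descriptors cannot.

Every descriptor maps to one of 14 semantic parameter classes (size,
polarity, ring topology, functional groups, …). Forward subset selection
walks parameter counts N = 1, 2, …, accepting the best (N+1)-parameter
model only when its 4-fold batch-jackknife cross-validated mean ROC
improves by more than 0.009, with a local-minimum guard; the class of
the best one-parameter model is the *primary* parameter. A balanced
random forest (500 Gini trees, depth ≤ 20, ≥ 10 samples per node,
√p split candidates, equalized class sizes) validates the result through
percent selection frequency z-scores with a 2.1 importance cutoff.

## Worked example

```python
import fragmind as fm
from fragmind import synthetic_data as syn, model_selection as msel
from fragmind.snb import CVEngine

# the study: 3,700 fragments, 8 batches, 227 duplicates
frags = fm.assign_batches(fm.generate_fragments(3700, seed=1), 8, 227, seed=2)
table = fm.compute_descriptors(frags)
roster = syn.ruleset_selectors() + syn.strategy_selectors()
matrix = syn.build_selection_matrix(roster, frags, table)
pres = frags.presentations()

# recover what the 2-rule selector (atoms>=15 AND TPSA<55, 5% noise) uses
result = msel.run_subset_search(matrix.row("rules2"), pres, table)
print(sorted(result.selected_parameters), round(result.selected_roc, 3))
# ['polarity', 'size'] 0.894

# the XOR selector is only learnable with a joint key
eng = CVEngine(matrix.row("strategy4"), pres, table)
print(round(eng.evaluate([("num_atoms", "tpsa")]).mean_roc, 3))  # 0.943
print(round(eng.evaluate(["num_atoms", "tpsa"]).mean_roc, 3))    # 0.534
```

The first block recovers exactly the two parameter classes the simulated
selector used, with a cross-validated ROC of 0.894 (the ceiling under 5%
label noise is ≈ 0.95). The second block shows the interdependency
contrast: treating atom count and polar surface area jointly represents
the XOR selection pattern (ROC 0.943), while the same two descriptors
used independently stay near chance (0.534).

A full pipeline — generation, descriptors, all selectors, SNB search,
RF validation, consensus and statistics, with a checksummed manifest —
runs from one command:

```
fragmind run --seed 0 --out results/
```

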