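# liemarkov

Lie Markov DNA substitution models: a catalogue of 37 rate-matrix
structures (99 pairing variants; 108 models with the classical
reversible panel), with stochastic parameterization, multiplicative
closure and embeddability diagnostics, maximum-likelihood fitting and
sequence simulation.

## The problem

Phylogenetic inference models DNA evolution with a rate matrix `Q`
whose exponential gives substitution probabilities along each branch.
Real lineages do not evolve under one constant process: rates drift
over time. When the process changes along a branch, the data are
explained by an *average* rate matrix
`Q' = log(exp(Q1·t1) exp(Q2·t2)) / (t1+t2)`. For most standard models —
including GTR, the workhorse of the field — `Q'` generally falls
*outside* the model: the model class is not closed under this kind of
mixing, so fitting it to a heterogeneous lineage is self-inconsistent.

A model whose rate matrices form a linear space closed under the matrix
commutator (a Lie algebra) does not have this defect: whenever `Q'` is
a real rate matrix it stays inside the model. This package implements
the complete hierarchy of such DNA models that respect a
purine/pyrimidine-style pairing of bases, from the 1-parameter
Jukes-Cantor model (`1.1`) to the 12-parameter general Markov model
(`12.12`). Most members are *nonreversible* and allow base composition
to drift — unlike the reversible panel. The package provides:

- a registry of all structures, pairing variants (RY/WS/MK), aliases,
  nesting relations, reversibility flags and equilibrium-frequency
  degrees of freedom;
- the Cartesian parameterization mapping a unit hypercube onto exactly
  the stochastic members of each model (the property that makes
  hill-climbing likelihood optimization work), plus extreme-ray
  enumeration of each model's stochastic cone;
- Monte Carlo embeddability experiments (when does the average of two
  model members leave the stochastic cone?);
- a pruning-algorithm likelihood engine with invariant-site and
  discrete-gamma heterogeneity, BIC/AICc model scans over the full
  catalogue, and a deterministic sequence simulator.

See `docs/methods.md` for conventions, algorithms and limitations.

## Worked example

Simulate an alignment under the nonreversible five-parameter model
`RY5.6b` on a four-taxon tree, then recover the generating parameters
and compare models. First, the rate matrix we will simulate under
(Cartesian parameters `b`, alphabetical base order, columns sum to
zero):

```text
$ cat tree.nwk
((human:0.08,chimp:0.05):0.06,(mouse:0.25,rat:0.21):0.12);

$ liemarkov matrix --model RY5.6b -b 0.5,0.3,0.25,-0.35
# liemarkov rate matrix; base order ACGT; columns sum to zero
-0.9202898550724639 0.3405797101449276 0.5579710144927538 0.3405797101449276
0.16666666666666669 -1.0942028985507248 0.16666666666666669 0.3840579710144928
0.48550724637681164 0.26811594202898553 -0.9927536231884059 0.26811594202898553
0.26811594202898553 0.48550724637681164 0.26811594202898553 -0.9927536231884059

$ liemarkov simulate tree.nwk --model RY5.6b -b 0.5,0.3,0.25,-0.35 \
      --sites 2000 --seed 42 -o example.fasta
# command=simulate model=RY5.6b sites=2000 seed=42 rate_model=single version=1.0.0
```

Fit the generating model (output truncated to the interesting fields):

```text
$ liemarkov fit example.fasta --tree tree.nwk --model RY5.6b --restarts 1 --seed 1
{
  "model": "RY5.6b",
  "lnL": -7412.592226640199,
  "k": 10,
  "BIC": 14901.19347787582,
  "AICc": 14845.2950616263,
  "parameters": {
    "b": [
      0.4983616577259881,
      0.31733025583452484,
      0.27852235103874523,
      -0.39279453846109563
    ]
  },
  ...
}
```

The true `b = (0.5, 0.3, 0.25, -0.35)` is recovered to within sampling
error at 2000 sites. Now compare against neighbours in the hierarchy
and two reversible panel models:

```text
$ liemarkov scan example.fasta --tree tree.nwk --panel names \
      --models 1.1,RY2.2b,3.3a,RY5.6b,HKY,GTR --seed 1 --restarts 1
model	heterogeneity	lnL	k	BIC	AICc	dBIC	dAICc
HKY	single	-7415.311987	9	14899.032096	14848.714426	0.000000	3.419365
RY5.6b	single	-7412.592227	10	14901.193478	14845.295062	2.161382	0.000000
GTR	single	-7411.845265	13	14922.502262	14849.873813	23.470166	4.578751
RY2.2b	single	-7485.170717	6	15015.946848	14982.383581	116.914752	137.088519
3.3a	single	-7485.125059	7	15023.456435	14984.306343	124.424339	139.011281
1.1	single	-7524.232486	5	15086.469483	15058.495061	187.437387	213.200000
```

An honest result: at 2000 sites the generating model wins on AICc while
the cheaper HKY edges it on BIC by 2.2 units — model selection at this
scale genuinely cannot tell them apart, and both crush the
underparameterized models.

Embeddability of the least-closed model in the hierarchy (at what trace
do 5% of random two-epoch averages leave the stochastic cone?):

```text
$ liemarkov embeddability --model 10.12 --target 0.05 -n 500 --seed 1
{"model": "RY10.12", "status": "crossed", "trace": -3.8938672444977476, "ci_halfwidth": 0.4374055547991082, "n": 500}
```

The same machinery is available from Python:

```python
from liemarkov import get_model, CartesianParams, cartesian_to_rate

model = get_model("RY5.6b")          # or "K2ST", "GTR", "WS6.6", ...
Q = cartesian_to_rate(CartesianParams(model, [0.5, 0.3, 0.25, -0.35]))
```

## Repository layout

- `src/liemarkov/` — the package (`basis`, `registry`, `rates`,
  `cartesian`, `embeddability`, `reversible`, `alignment`, `trees`,
  `likelihood`, `simulate`, `cli`).
- `tests/` — pytest suite, including the acceptance criteria.
- `scripts/acceptance.py` — standalone recomputation of the numeric
  targets.
- `docs/methods.md` — methods note.
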