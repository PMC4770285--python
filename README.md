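# cleavstat

Statistical prediction of protein structure-associated properties from the
mass distributions of proteolytic cleavage fragments.

## The problem

Peptide-mass fingerprinting identifies a protein by matching the fragment
masses observed after an amino-acid-specific proteolytic cleavage (e.g. a
MALDI-TOF spectrum of a tryptic digest) against simulated digests of known
sequences. When no homologous sequence is in the database, the spectrum
itself still carries structural information: for a cleavage at specific
residues, the fragment sizes are the intervals between consecutive cleavage
sites, and those intervals reflect how the residues are *arranged* along the
chain. Randomly arranged residues give exponentially distributed intervals;
structured arrangements — e.g. the hydrophobic segments of α-helical
transmembrane proteins — give distributions much broader than exponential.
`cleavstat` turns this observation into a classifier that needs only a list
of fragment masses, never the sequence itself.

## The statistic

For a digest with fragment masses *m₁ … m_N* and mean mass *M*, form the
normalized masses *x = m/M* and their empirical exceedance distribution
*R*(*x*) = P(*X* > *x*). Under the random-arrangement null, *R*(*x*) ≈
e^(−*x*). The deviation statistic is the Kolmogorov distance

    K_stat = max over observed x of [ R_emp(x) − e^(−x) ]        (signed)
    K_stat = max over observed x of | R_emp(x) − e^(−x) |        (absolute)

computed per protein and per cleavage rule. Sixteen built-in cleavage rules
(trypsin `KR`, thermolysin `AFILMV`, CNBr `M`, …, each with its contextual
exceptions such as no cleavage of Lys–Pro bonds) give a 16-dimensional
feature vector per protein. Decision layers on top of it:

* single-rule thresholding with ROC/AUC analysis (AUC below 0.5 flags an
  inverted decision rule; efficacy is then 1 − AUC);
* stepwise binary logistic regression (Mann–Whitney prescreen, entry by
  single-predictor Wald statistic, stop on vanishing AUC gain, Nagelkerke
  R²);
* stepwise linear discriminant analysis for ≥ 3 classes (entry by the
  Mahalanobis distance between the two closest groups).

A synthetic-sequence module generates i.i.d. (null) and Markov-modulated
"patchy" proteins so the entire pipeline is testable end to end without
external data.

## Worked example

```python
import cleavstat as cs

# tryptic digest of a 60-residue chain and its deviation from the null
rec = cs.ProteinRecord("demo", "MKWVTFISLLFLFSSAYSRGVFRRDAHKSEVAHRFKDLGEENFKALVLIAFAQYLQQCPF")
frags = cs.digest(rec, cs.get_rule("KR"))
spectrum = cs.MassSpectrum.from_fragments(frags)
res = cs.kstat(spectrum, mode="absolute")
print("N =", spectrum.N, " M =", round(spectrum.M, 2), "Da")
print("K_stat =", round(res.value, 4),
      " p =", round(cs.kolmogorov_pvalue(res.value, res.N), 4))
```

prints

```
N = 9  M = 800.37 Da
K_stat = 0.1062  p = 1.0
```

— nine tryptic fragments of mean mass 800 Da whose normalized mass
distribution deviates from e^(−x) by at most 0.106, far below any rejection
threshold at N = 9: this single digest looks random-arranged.

Group-level classification on synthetic data:

```python
recs, labels = cs.make_benchmark(cs.patchy_spec(100, seed=1),
                                 cs.random_spec(100, seed=101),
                                 labels=("patchy", "random"))
feats = cs.kstat_features(recs, rules=["AFILMV"], mode="absolute")
k_patchy = feats.loc[[i for i in feats.index if labels[i] == "patchy"], "AFILMV"]
k_random = feats.loc[[i for i in feats.index if labels[i] == "random"], "AFILMV"]
print(f"mean K_stat: patchy {k_patchy.mean():.3f}, random {k_random.mean():.3f}")
print(f"thermolysin-rule AUC = {cs.roc(k_random, k_patchy).auc:.3f}")
```

prints

```
mean K_stat: patchy 0.358, random 0.203
thermolysin-rule AUC = 0.965
```

— hydrophobically patchy chains (a stand-in for α-helical transmembrane
proteins) deviate almost twice as far from the exponential null as
composition-matched random chains, and the single thermolysin rule already
separates the groups at AUC 0.97.

The same stages are scriptable from the shell:

```sh
cleavstat simulate --preset patchy --n 100 --seed 1 --out patchy.fasta
cleavstat kstat --fasta patchy.fasta --rules all --mode absolute --out features.csv
cleavstat roc --features features.csv --labels labels.tsv --rule AFILMV
cleavstat train --features features.csv --labels labels.tsv --out model.json
cleavstat predict --model model.json --features features.csv
```

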