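# sepsaki

Knowledge-aware risk prediction of acute kidney injury (AKI) in sepsis,
with KDIGO-style diagnostic staging, adversarial multicenter domain
adaptation and decision-curve evaluation.

## Who this is for

Sepsis-associated AKI is common in the ICU and carries high mortality;
early identification of high-risk patients is the point of intervention.
Two practical obstacles shape this package:

1. **Diagnosis and grading.**  AKI is diagnosed and staged from serum
   creatinine (SCr, μmol/L) dynamics and urine output (ml/kg/h), with
   absorbing overrides for renal replacement therapy and paediatric
   patients with low GFR.  `sepsaki.staging` implements a configurable
   three-stage rules engine over timestamped patient timelines, with a
   full audit trail of which rule fired in which time window.
2. **Multicenter transfer.**  A risk model trained on one labelled
   hospital cohort (the *source*) degrades on another hospital (the
   *target*) whose feature distribution differs, P_s(x) ≠ P_t(x).
   `sepsaki.risk` trains a classifier whose internal representation is
   made center-invariant by an adversarial discriminator, so the
   source-trained classifier transfers to the unlabelled target center.

Clinical knowledge enters as a knowledge graph of concept triples
(head, relation, tail).  `sepsaki.embedding` learns entity embeddings
with relation-specific graph-convolution layers and DistMult scoring;
each patient's linked concepts are averaged into a knowledge feature
x^k that is fused with the clinical features by a co-attention block.

No real multicenter cohort or clinical knowledge graph is bundled:
`sepsaki.simulate` generates both — a planted-community graph and two
Gaussian centers under covariate shift with a known logistic outcome
model — with the full ground truth needed to score any model.

## The model

**Knowledge embedding.**  Entity vectors h are propagated through two
relational graph-convolution layers

    h_i ← ReLU( Σ_r Σ_{j∈N_i^r} (1/|N_i^r|) W_r h_j + W_o h_i ),

triples are scored by DistMult, s(e_i, r, e_j) = σ(h_i^T R_r h_j) with
R_r diagonal, and all parameters are trained against uniformly
corrupted triples under the cross-entropy loss
L_g = −(1/2|Γ|) Σ [y log s + (1−y) log(1−s)].

**Risk network.**  Linear encoders give latents z^p (clinical) and z^k
(knowledge); a linear decoder reconstructs x^k with mean-squared loss
L_rec.  Co-attention derives α^p, α^k from the row/column means of the
correlation matrix M = z^p (z^k)^T, gates each view with the other,

    B^P = tanh(U_p1 (z^p + α^p ⊙ z^k)),  B^K = tanh(U_k1 (z^k + α^k ⊙ z^p)),

and forms the representation π(x) = [B^P ⊙ z^p ; B^K ⊙ z^k].  A softmax
classifier C minimises cross-entropy L_cls on labelled source patients
while a sigmoid discriminator D_adv minimises
L_adv = −E_s log D(π) − E_t log(1−D(π)); a gradient-reversal layer feeds
−λ1 ∂L_adv back into the representation.  The joint objective is

    L = L_cls + λ1 L_adv + λ2 L_rec.

**Evaluation.**  Sensitivity/specificity/accuracy at a cutoff, rank
(Mann–Whitney) AUC, and decision-curve analysis: net benefit
NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) against the treat-all line
π − (1−π)·p_t/(1−p_t) and the treat-none line at zero.

## Worked example

```python
import numpy as np
from sklearn.metrics import roc_auc_score
from sepsaki import (AKIRiskModel, CohortSpec, KGEmbeddingModel, KGSpec,
                     PatientTimeline, ScoredCohort, ScrMeasurement,
                     UrineEpoch, auc, benefit_range, confusion_metrics,
                     decision_curve, make_cohort, make_kg, stage_aki)
from sepsaki.io import knowledge_feature_frame

# --- stage one patient: SCr 100 -> 230 μmol/L within 72 h -------------
patient = PatientTimeline(
    patient_id="icu-042",
    scr=[ScrMeasurement(0.0, 100.0), ScrMeasurement(72.0, 230.0)],
    urine=[UrineEpoch(0.0, 96.0, 1.0)],
    age=50.0, rrt=False)
result = stage_aki(patient)
print(result.stage)                    # 2   (SCr reached 2.3x baseline)
print(result.comprehensive_positive)   # True (1.8x within one week)

# --- synthetic two-center study ---------------------------------------
kg, communities = make_kg(KGSpec(seed=0))
emb = KGEmbeddingModel(kg, d_e=16, n_layers=2).fit(epochs=200, seed=0)
print(emb.summary())

cohort, truth = make_cohort(CohortSpec(seed=0), kg, communities)
xcols = [f"x{j}" for j in range(10)]
ks = knowledge_feature_frame(cohort.links, emb.state,
                             cohort.source["patient_id"].tolist())
kt = knowledge_feature_frame(cohort.links, emb.state,
                             cohort.target["patient_id"].tolist())
kc = [c for c in ks.columns if c != "patient_id"]

model = AKIRiskModel(cohort.source[xcols].to_numpy(), ks[kc].to_numpy(),
                     truth.source_labels,
                     cohort.target[xcols].to_numpy(), kt[kc].to_numpy())
res = model.fit(lam1=0.1, lam2=0.1, epochs=300, seed=0)
print(res.summary())

risk = res.predict_proba(cohort.target[xcols].to_numpy(),
                         kt[kc].to_numpy())[:, 1]
scored = ScoredCohort(risk, truth.target_labels)   # hidden labels
sens, spec, acc = confusion_metrics(scored, 0.5)
print(sens, spec, acc, auc(scored))
print(benefit_range(decision_curve(scored)))
```

Output (abridged):

```
2
True
Knowledge-graph embedding (relational GCN + DistMult)
...
final triple loss:   0.168112
held-out triple AUC: 0.9235
Knowledge-aware adversarial AKI risk model
...
final classifier loss       0.049982
final adversarial loss      1.344538
final reconstruction loss   0.044698
final joint objective       0.188905
0.964 0.934 0.946 0.983
(0.01, 0.96)
```

Reading the numbers: the embedding classifies held-out knowledge-graph
triples with AUC 0.92, so the planted concept structure was recovered.
The adversarial loss settles near 2·log 2 ≈ 1.386 — the discriminator
cannot tell the centers apart, i.e. the representation is
center-invariant — while the target-center AUC against the generator's
hidden labels is 0.983.  The decision curve beats both the treat-all
and treat-none policies for risk thresholds between 0.01 and 0.96, the
range over which acting on the model's predictions yields positive net
clinical benefit.

## Command line

The same pipeline as shell commands (every command takes `--seed`;
reruns are byte-identical):

```sh
sepsaki simulate --out study --seed 7
sepsaki train-kg --triples study/triples.tsv --seed 7 --out study/kg.json
sepsaki train --source study/source.csv --target study/target.csv \
    --kg-state study/kg.json --links study/links.tsv --seed 7 \
    --out study/model.json
sepsaki predict --model study/model.json --input study/source.csv \
    --kg-state study/kg.json --links study/links.tsv --out study/pred.csv
sepsaki stage --patients study/records.csv --meta study/patients.csv \
    --out study/stages.csv
sepsaki evaluate --pred study/pred.csv --out study/metrics.json
sepsaki dca --pred study/pred.csv --out study/curve.tsv
```

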