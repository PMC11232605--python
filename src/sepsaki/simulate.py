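"""Synthetic study data with full ground truth.

Real multicenter sepsis-AKI cohorts and the image-derived knowledge map
are not publicly deposited, so every other module is exercised on
simulated stand-ins:

* ``make_kg`` — a planted-community knowledge graph: entities split into
  communities, triples drawn independently per ordered pair and relation
  with a higher probability inside than between communities.  Embedding
  models can recover this structure, giving a known target for held-out
  triple classification.
* ``make_cohort`` — two patient centers under covariate shift: source
  features ~ N(0, I), target features ~ N(δ, I), with a *shared*
  logistic labelling function P(y=1|x) = σ(βᵀx + b), optional label
  noise, and per-patient concept links biased toward the community
  matching the label (so knowledge features carry outcome signal).
  Target labels are generated but withheld from the returned tables;
  they live only in the ground-truth manifest.
* ``make_timelines`` — creatinine/urine timelines consistent with the
  outcome label, for exercising the staging engine end to end.
* ``write_fixtures`` — emits everything in the exact delimited formats
  the other modules read.

All generators are pure functions of their spec: same spec, same bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._util import atomic_write_text, child_seed
from .exceptions import ValidationError
from .kg import KnowledgeGraph, write_triples
from .staging import PatientTimeline, ScrMeasurement, UrineEpoch

__all__ = ["KGSpec", "CohortSpec", "CohortPair", "GroundTruthManifest",
           "make_kg", "make_cohort", "make_timelines", "write_fixtures"]


@dataclass(frozen=True)
class KGSpec:
    """Planted-community knowledge-graph recipe."""
    n_entities: int = 40
    n_relations: int = 3
    n_communities: int = 2
    p_within: float = 0.9
    p_between: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_entities < 1:
            raise ValidationError("n_entities must be >= 1")
        if self.n_relations < 1 or self.n_communities < 1:
            raise ValidationError("need >= 1 relation and community")
        for p in (self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.p_within <= self.p_between:
            raise ValidationError(
                "p_within must exceed p_between for learnable structure")


@dataclass(frozen=True)
class CohortSpec:
    """Two-center cohort recipe.

    `shift` is the difference of center feature means (δ); `beta` and
    `intercept` define the shared logistic outcome model; `link_rate` is
    the mean number of knowledge-graph concept links per patient and
    `link_bias` the probability each link lands in the community matching
    the patient's outcome.

    By default β loads on the first six features and δ (2 standard
    deviations) on the remaining ones, so the centers differ only in
    outcome-irrelevant directions: the labelling function *and* the
    outcome prevalence are shared, which is the covariate-shift regime
    where adversarial alignment can fully remove the center signal
    without destroying outcome information.
    """
    n_source: int = 500
    n_target: int = 500
    p: int = 10
    shift: Optional[tuple] = None      # default: 2.0 beyond feature 6
    beta: Optional[tuple] = None       # default: alternating ±0.8, 6 terms
    intercept: float = -0.5
    link_rate: float = 3.0
    link_bias: float = 0.8
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_source < 1 or self.n_target < 1:
            raise ValidationError("both centers need at least one patient")
        if self.p < 1:
            raise ValidationError("feature dimension must be >= 1")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValidationError("label_noise must lie in [0, 1]")
        if not 0.0 <= self.link_bias <= 1.0:
            raise ValidationError("link_bias must lie in [0, 1]")
        if self.shift is not None and len(self.shift) != self.p:
            raise ValidationError(
                f"shift has length {len(self.shift)}, expected p={self.p}")
        if self.beta is not None and len(self.beta) != self.p:
            raise ValidationError(
                f"beta has length {len(self.beta)}, expected p={self.p}")

    def shift_vector(self) -> np.ndarray:
        if self.shift is not None:
            return np.asarray(self.shift, dtype=float)
        delta = np.zeros(self.p)
        delta[min(6, self.p):] = 2.0
        return delta

    def beta_vector(self) -> np.ndarray:
        if self.beta is not None:
            return np.asarray(self.beta, dtype=float)
        beta = np.zeros(self.p)
        k = min(6, self.p)
        beta[:k] = [0.8 * (-1) ** i for i in range(k)]
        return beta


@dataclass
class CohortPair:
    """Labelled source table, unlabelled target table and concept links.

    Tables carry columns patient_id, center, label (empty for target)
    and x0..x{p-1}; links pair patient_id with entity_id.
    """
    source: pd.DataFrame
    target: pd.DataFrame
    links: pd.DataFrame


@dataclass
class GroundTruthManifest:
    """Everything needed to score a model without re-simulation."""
    beta: np.ndarray
    intercept: float
    shift: np.ndarray
    source_labels: np.ndarray
    target_labels: np.ndarray          # hidden from the tables
    center_labels: dict                # patient_id -> center
    communities: dict                  # entity -> community (if KG given)
    bayes_auc: float
    seeds: dict

    def to_json(self) -> str:
        return json.dumps({
            "format": "sepsaki-manifest", "version": 1,
            "beta": self.beta.tolist(), "intercept": self.intercept,
            "shift": self.shift.tolist(),
            "source_labels": self.source_labels.tolist(),
            "target_labels": self.target_labels.tolist(),
            "center_labels": self.center_labels,
            "communities": self.communities,
            "bayes_auc": self.bayes_auc, "seeds": self.seeds,
        })

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(beta=np.array(d["beta"]), intercept=d["intercept"],
                   shift=np.array(d["shift"]),
                   source_labels=np.array(d["source_labels"]),
                   target_labels=np.array(d["target_labels"]),
                   center_labels=d["center_labels"],
                   communities=d["communities"],
                   bayes_auc=d["bayes_auc"], seeds=d["seeds"])


def make_kg(spec: KGSpec) -> tuple[KnowledgeGraph, dict]:
    """Sample a planted-community graph; returns the graph and the
    entity -> community assignment."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(max(spec.n_entities - 1, 1)))
    entities = [f"c{i:0{width}d}" for i in range(spec.n_entities)]
    communities = {e: (i * spec.n_communities) // spec.n_entities
                   for i, e in enumerate(entities)}
    relations = [f"r{k}" for k in range(spec.n_relations)]
    triples = set()
    for rel in relations:
        for i, ei in enumerate(entities):
            for j, ej in enumerate(entities):
                if i == j:
                    continue
                prob = (spec.p_within
                        if communities[ei] == communities[ej]
                        else spec.p_between)
                if rng.random() < prob:
                    triples.add((ei, rel, ej))
    if not triples:
        # tiny graphs can come out empty; guarantee one within-community
        # edge so downstream modules have something to chew on
        triples.add((entities[0], relations[0],
                     entities[min(1, spec.n_entities - 1)]))
    return (KnowledgeGraph(tuple(entities), tuple(relations),
                           frozenset(triples)),
            communities)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_cohort(spec: CohortSpec, kg: Optional[KnowledgeGraph] = None,
                communities: Optional[dict] = None
                ) -> tuple[CohortPair, GroundTruthManifest]:
    """Simulate the two centers, their hidden labels and concept links."""
    rng = np.random.default_rng(child_seed(spec.seed, "cohort"))
    beta = spec.beta_vector()
    delta = spec.shift_vector()
    Xs = rng.normal(0.0, 1.0, (spec.n_source, spec.p))
    Xt = rng.normal(0.0, 1.0, (spec.n_target, spec.p)) + delta
    ps = _sigmoid(Xs @ beta + spec.intercept)
    pt = _sigmoid(Xt @ beta + spec.intercept)
    ys = (rng.random(spec.n_source) < ps).astype(int)
    yt = (rng.random(spec.n_target) < pt).astype(int)
    if spec.label_noise > 0:
        ys = np.where(rng.random(spec.n_source) < spec.label_noise,
                      rng.integers(0, 2, spec.n_source), ys)
        yt = np.where(rng.random(spec.n_target) < spec.label_noise,
                      rng.integers(0, 2, spec.n_target), yt)

    ids_s = [f"s{i:04d}" for i in range(spec.n_source)]
    ids_t = [f"t{i:04d}" for i in range(spec.n_target)]
    xcols = [f"x{j}" for j in range(spec.p)]
    source = pd.DataFrame(Xs, columns=xcols)
    source.insert(0, "patient_id", ids_s)
    source.insert(1, "center", "source")
    source.insert(2, "label", ys)
    target = pd.DataFrame(Xt, columns=xcols)
    target.insert(0, "patient_id", ids_t)
    target.insert(1, "center", "target")
    target.insert(2, "label", pd.array([pd.NA] * spec.n_target,
                                       dtype="Int64"))

    links_rows = []
    if kg is not None:
        if communities is None:
            raise ValidationError(
                "community assignment required when a KG is supplied")
        n_comm = max(communities.values()) + 1
        by_comm = {c: [e for e in kg.entities if communities[e] == c]
                   for c in range(n_comm)}
        all_ents = list(kg.entities)
        link_rng = np.random.default_rng(child_seed(spec.seed, "links"))
        for pid, y in zip(ids_s + ids_t, np.concatenate([ys, yt])):
            n_links = max(1, int(link_rng.poisson(spec.link_rate)))
            target_comm = int(y) % n_comm
            chosen = set()
            for _ in range(n_links):
                pool = (by_comm[target_comm]
                        if link_rng.random() < spec.link_bias
                        else all_ents)
                chosen.add(pool[link_rng.integers(len(pool))])
            for e in sorted(chosen):
                links_rows.append((pid, e))
    links = pd.DataFrame(links_rows, columns=["patient_id", "entity_id"])

    p_all = np.concatenate([ps, pt])
    y_all = np.concatenate([ys, yt])
    if y_all.min() == y_all.max():
        bayes_auc = float("nan")
    else:
        from sklearn.metrics import roc_auc_score
        bayes_auc = float(roc_auc_score(y_all, p_all))
    manifest = GroundTruthManifest(
        beta=beta, intercept=spec.intercept, shift=delta,
        source_labels=ys, target_labels=yt,
        center_labels={**{i: "source" for i in ids_s},
                       **{i: "target" for i in ids_t}},
        communities=dict(communities) if communities else {},
        bayes_auc=bayes_auc,
        seeds={"cohort": child_seed(spec.seed, "cohort"),
               "links": child_seed(spec.seed, "links"),
               "master": spec.seed})
    return CohortPair(source=source, target=target, links=links), manifest


def make_timelines(cohort: CohortPair, manifest: GroundTruthManifest,
                   seed: int = 0) -> list[PatientTimeline]:
    """Creatinine/urine timelines consistent with each patient's outcome:
    AKI patients ramp creatinine to 1.7–2.6x baseline over four days and
    may show an oliguric window; non-AKI patients fluctuate mildly."""
    rng = np.random.default_rng(child_seed(seed, "timelines"))
    labels = dict(zip(cohort.source["patient_id"],
                      manifest.source_labels))
    labels.update(zip(cohort.target["patient_id"],
                      manifest.target_labels))
    timelines = []
    for pid in list(cohort.source["patient_id"]) + \
            list(cohort.target["patient_id"]):
        y = int(labels[pid])
        base = rng.uniform(60.0, 110.0)
        times = np.arange(0.0, 97.0, 12.0)
        if y == 1:
            peak = rng.uniform(1.7, 2.6)
            ramp = 1.0 + (peak - 1.0) * (times / times[-1])
        else:
            ramp = 1.0 + rng.uniform(-0.05, 0.15, len(times))
            ramp[0] = 1.0
        scr = [ScrMeasurement(t, base * max(r, 0.5))
               for t, r in zip(times, ramp)]
        urine = []
        oliguric = y == 1 and rng.random() < 0.5
        for k in range(12):
            rate = (rng.uniform(0.2, 0.4)
                    if oliguric and 4 <= k < 6 + rng.integers(0, 2)
                    else rng.uniform(0.8, 1.5))
            urine.append(UrineEpoch(8.0 * k, 8.0 * (k + 1), rate))
        timelines.append(PatientTimeline(
            patient_id=pid, scr=scr, urine=urine,
            age=float(rng.integers(20, 90)), rrt=False, gfr=None))
    return timelines


def _float_fmt(x: float) -> str:
    return repr(float(x))


def write_fixtures(out_dir, kg_spec: KGSpec = KGSpec(),
                   cohort_spec: CohortSpec = CohortSpec(),
                   timelines_seed: int = 0) -> dict:
    """Generate a full synthetic study and write every artifact in the
    dialects the other modules read.  Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kg, communities = make_kg(kg_spec)
    cohort, manifest = make_cohort(cohort_spec, kg, communities)
    timelines = make_timelines(cohort, manifest, seed=timelines_seed)

    paths = {
        "triples": out / "triples.tsv",
        "links": out / "links.tsv",
        "source": out / "source.csv",
        "target": out / "target.csv",
        "records": out / "records.csv",
        "meta": out / "patients.csv",
        "manifest": out / "manifest.json",
    }
    write_triples(kg, paths["triples"])
    atomic_write_text(paths["links"], cohort.links.to_csv(
        sep="\t", index=False))
    atomic_write_text(paths["source"],
                      cohort.source.to_csv(index=False))
    atomic_write_text(paths["target"],
                      cohort.target.to_csv(index=False))

    rec_lines = ["patient_id,record_type,time_h,start_h,end_h,value"]
    meta_lines = ["patient_id,age,rrt,gfr,historical_baseline_scr"]
    for tl in timelines:
        for m in tl.scr:
            rec_lines.append(
                f"{tl.patient_id},scr,{_float_fmt(m.time)},,,"
                f"{_float_fmt(m.value)}")
        for e in tl.urine:
            rec_lines.append(
                f"{tl.patient_id},urine,,{_float_fmt(e.start)},"
                f"{_float_fmt(e.end)},{_float_fmt(e.rate)}")
        gfr = "" if tl.gfr is None else _float_fmt(tl.gfr)
        hist = ("" if tl.historical_baseline_scr is None
                else _float_fmt(tl.historical_baseline_scr))
        meta_lines.append(
            f"{tl.patient_id},{_float_fmt(tl.age)},"
            f"{int(tl.rrt)},{gfr},{hist}")
    atomic_write_text(paths["records"], "\n".join(rec_lines) + "\n")
    atomic_write_text(paths["meta"], "\n".join(meta_lines) + "\n")
    atomic_write_text(paths["manifest"], manifest.to_json())
    return {k: str(v) for k, v in paths.items()}
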