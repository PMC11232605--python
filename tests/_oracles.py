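"""Independent slow oracles used to cross-check the implementation.

Each oracle re-derives a quantity by exhaustive enumeration or explicit
loops, sharing no code with the package's vectorised/scanning paths.
"""

from __future__ import annotations

import numpy as np

from sepsaki.staging import (PatientTimeline, ScrMeasurement,
                             StagingThresholds, UrineEpoch)


def oracle_scr_stage(tl: PatientTimeline, th: StagingThresholds) -> int:
    """Exhaustive pairwise scan over all SCr measurements."""
    base = (tl.historical_baseline_scr
            if tl.historical_baseline_scr is not None else tl.scr[0].value)
    t0 = tl.scr[0].time
    stage = 0
    for j, mj in enumerate(tl.scr):
        if mj.time - t0 > 168.0:
            continue
        ratio = mj.value / base
        rise = max((mj.value - mi.value
                    for mi in tl.scr[:j + 1]
                    if mj.time - mi.time <= 48.0), default=0.0)
        if ratio > th.s3_ratio * (1 + th.rtol) or \
                mj.value >= th.s3_abs_umol * (1 - th.rtol):
            stage = max(stage, 3)
        elif ratio >= th.s2_ratio * (1 - th.rtol):
            stage = max(stage, 2)
        elif ratio >= th.s1_ratio * (1 - th.rtol) or \
                rise >= th.s1_rise_umol * (1 - th.rtol):
            stage = max(stage, 1)
    return stage


def oracle_urine_stage(tl: PatientTimeline, th: StagingThresholds) -> int:
    """Enumerate every contiguous sub-window of the urine epochs."""
    eps = sorted(tl.urine, key=lambda e: e.start)
    stage = 0
    n = len(eps)
    for i in range(n):
        for j in range(i, n):
            win = eps[i:j + 1]
            if any(win[k + 1].start != win[k].end
                   for k in range(len(win) - 1)):
                continue
            dur = win[-1].end - win[0].start
            mx = max(e.rate for e in win)
            if mx < th.s3_uo_rate and dur > th.s3_uo_hours * (1 + th.rtol):
                stage = max(stage, 3)
            if mx == 0.0 and dur > th.s3_anuria_hours * (1 + th.rtol):
                stage = max(stage, 3)
            if mx < th.s2_uo_rate and dur > th.s2_uo_hours * (1 + th.rtol):
                stage = max(stage, 2)
            if mx < th.s1_uo_rate and \
                    dur >= th.s1_uo_min_hours * (1 - th.rtol):
                stage = max(stage, 1)
    return stage


def oracle_stage(tl: PatientTimeline, th: StagingThresholds) -> int:
    stage = max(oracle_scr_stage(tl, th), oracle_urine_stage(tl, th))
    if tl.rrt:
        stage = 3
    if tl.age < th.pediatric_age and tl.gfr is not None \
            and tl.gfr < th.pediatric_gfr:
        stage = 3
    return stage


def oracle_gcn_layer(h: np.ndarray, w_rel: np.ndarray, w_self: np.ndarray,
                     neighbor_sets: dict) -> np.ndarray:
    """Entity-by-entity loop evaluation of the relational GCN update.

    `neighbor_sets[(i, r)]` is the list of neighbour indices of entity i
    under relation r.
    """
    n, d = h.shape
    n_rel = w_rel.shape[0]
    out = np.zeros_like(h)
    for i in range(n):
        acc = w_self @ h[i]
        for r in range(n_rel):
            nbrs = neighbor_sets.get((i, r), [])
            if not nbrs:
                continue
            for j in nbrs:
                acc = acc + (w_rel[r] @ h[j]) / len(nbrs)
        out[i] = np.maximum(acc, 0.0)
    return out


def oracle_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute force over all positive-negative pairs, ties count half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_timeline(rng: np.random.Generator,
                    max_events: int = 20) -> PatientTimeline:
    """Random small timeline for staging oracle comparisons."""
    n_scr = int(rng.integers(1, max(2, max_events // 2)))
    times = np.sort(rng.uniform(0, 200, n_scr))
    times = times + np.arange(n_scr) * 1e-3  # break exact duplicates
    base = rng.uniform(40, 150)
    scr = [ScrMeasurement(float(t),
                          float(base * rng.uniform(0.5, 3.0)))
           for t in times]
    n_uo = int(rng.integers(0, max_events // 2))
    urine = []
    t = float(rng.uniform(0, 24))
    for _ in range(n_uo):
        dur = float(rng.uniform(1, 15))
        rate = float(rng.choice([0.0, rng.uniform(0.05, 1.6)]))
        urine.append(UrineEpoch(t, t + dur, rate))
        t += dur + float(rng.choice([0.0, rng.uniform(0.5, 8)]))
    return PatientTimeline(
        patient_id="rnd", scr=scr, urine=urine,
        historical_baseline_scr=(float(base)
                                 if rng.random() < 0.3 else None),
        age=float(rng.uniform(1, 95)), rrt=bool(rng.random() < 0.1),
        gfr=float(rng.uniform(10, 120)) if rng.random() < 0.3 else None)
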