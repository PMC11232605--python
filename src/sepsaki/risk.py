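"""Knowledge-aware, domain-adapted AKI risk prediction network.

Architecture (all linear maps are affine; d_z is the shared latent
dimension):

* two linear encoders map the raw clinical features x^p and the
  knowledge features x^k to latents z^p = W_p1 x^p + b_p1 and
  z^k = W_k1 x^k + b_k1; a linear decoder reconstructs
  x̂^k = W_k2 z^k + b_k2, penalised by the mean squared error L_rec;
* a co-attention block relates the two views through the correlation
  matrix M = z^p (z^k)^T, derives attention weights
  α^p = softmax(row-means of M), α^k = softmax(column-means of M),
  gates each view with the other,
  B^P = tanh(U_p1 (z^p + α^p ⊙ z^k)), B^K = tanh(U_k1 (z^k + α^k ⊙ z^p)),
  and emits the knowledge-aware representation
  π(x) = [B^P ⊙ z^p ; B^K ⊙ z^k] of length 2 d_z;
* a one-hidden-layer softmax classifier C predicts the K-way outcome on
  labelled source-center patients (cross-entropy L_cls);
* a one-hidden-layer sigmoid discriminator D_adv tries to tell source
  from target representations (cross-entropy L_adv); a gradient-reversal
  layer trains the representation to defeat it, so the classifier
  transfers to the unlabelled target center.

The joint objective is L_cls + λ1 L_adv + λ2 L_rec.  Optimisation is
full-batch SGD on the in-repo autodiff tape; an alternating min–max
scheme is available instead of gradient reversal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat, grad_reverse
from ._util import atomic_write_text, child_seed
from .exceptions import (ConfigError, NotFittedError, TrainingError,
                         ValidationError)

EPS = 1e-12  # probability clipping inside logs

__all__ = [
    "PatientSample", "encode", "reconstruction_loss", "correlation_matrix",
    "attention_weights", "fuse", "knowledge_aware_representation",
    "discriminator_loss", "classifier_loss", "joint_objective",
    "AKIRiskModel", "AKIRiskResults", "ModelState",
]


@dataclass(frozen=True)
class PatientSample:
    """One patient: raw clinical features x^p, knowledge features x^k,
    outcome label y (source-center only) and the center tag."""
    x_p: np.ndarray
    x_k: np.ndarray
    center: Literal["source", "target"]
    y: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "x_p", np.asarray(self.x_p, dtype=float))
        object.__setattr__(self, "x_k", np.asarray(self.x_k, dtype=float))
        if not (np.all(np.isfinite(self.x_p))
                and np.all(np.isfinite(self.x_k))):
            raise ValidationError("patient features must be finite")
        if self.center not in ("source", "target"):
            raise ValidationError(
                f"center must be 'source' or 'target', got {self.center!r}")
        if self.center == "source" and self.y is None:
            raise ValidationError("source-center samples must be labelled")
        if self.center == "target" and self.y is not None:
            raise ValidationError(
                "target-center samples are unlabelled by construction")


# ---------------------------------------------------------------------
# forward-pass operations (single-sample, plain numpy)
# ---------------------------------------------------------------------

def encode(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Linear encoder z = W x + b (no activation)."""
    x, W, b = (np.asarray(a, dtype=float) for a in (x, W, b))
    if W.shape[1] != x.shape[-1] or W.shape[0] != b.shape[0]:
        raise ConfigError(
            f"encoder shapes do not conform: W{W.shape}, x{x.shape}, "
            f"b{b.shape}")
    return x @ W.T + b


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean over the batch of the squared L2 reconstruction error
    ||x̂ - x||²  (1-D inputs are treated as a batch of one)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=float))
    if x.shape != x_hat.shape:
        raise ConfigError(
            f"reconstruction shapes differ: {x.shape} vs {x_hat.shape}")
    return float(np.mean(np.sum((x_hat - x) ** 2, axis=1)))


def correlation_matrix(z_p: np.ndarray, z_k: np.ndarray) -> np.ndarray:
    """Cross-view correlation M = z^p (z^k)^T; M[i, j] relates element i
    of the patient latent to element j of the knowledge latent."""
    z_p, z_k = np.asarray(z_p, dtype=float), np.asarray(z_k, dtype=float)
    if z_p.ndim != 1 or z_k.ndim != 1 or z_p.shape != z_k.shape:
        raise ConfigError(
            f"latents must be equal-length vectors, got {z_p.shape} "
            f"and {z_k.shape}")
    return np.outer(z_p, z_k)


def attention_weights(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """α^p = softmax of the row-means of M, α^k = softmax of the
    column-means; both are strictly positive and sum to one."""
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValidationError("correlation matrix must be finite")

    def softmax(v):
        e = np.exp(v - v.max())
        return e / e.sum()

    return softmax(M.mean(axis=1)), softmax(M.mean(axis=0))


def fuse(z_p, z_k, alpha_p, alpha_k, U_p1, U_k1):
    """Co-attention gates B^P = tanh(U_p1 (z^p + α^p ⊙ z^k)) and
    B^K = tanh(U_k1 (z^k + α^k ⊙ z^p)); entries lie in (-1, 1)."""
    z_p, z_k, alpha_p, alpha_k, U_p1, U_k1 = (
        np.asarray(a, dtype=float)
        for a in (z_p, z_k, alpha_p, alpha_k, U_p1, U_k1))
    d = z_p.shape[0]
    if not (z_k.shape == alpha_p.shape == alpha_k.shape == (d,)
            and U_p1.shape == U_k1.shape == (d, d)):
        raise ConfigError("fuse: shapes do not conform")
    b_p = np.tanh(U_p1 @ (z_p + alpha_p * z_k))
    b_k = np.tanh(U_k1 @ (z_k + alpha_k * z_p))
    return b_p, b_k


def knowledge_aware_representation(b_p, b_k, z_p, z_k) -> np.ndarray:
    """π(x) = [B^P ⊙ z^p ; B^K ⊙ z^k], length 2·d_z."""
    b_p, b_k, z_p, z_k = (np.asarray(a, dtype=float)
                          for a in (b_p, b_k, z_p, z_k))
    return np.concatenate([b_p * z_p, b_k * z_k])


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------

def discriminator_loss(d_adv, pi_source: np.ndarray,
                       pi_target: np.ndarray) -> float:
    """L_adv = -E_s[log D(π(x_s))] - E_t[log(1 - D(π(x_t)))].

    `d_adv` maps a (n, 2 d_z) batch of representations to center
    probabilities in (0, 1); probabilities are clipped before the logs.
    """
    pi_source = np.atleast_2d(np.asarray(pi_source, dtype=float))
    pi_target = np.atleast_2d(np.asarray(pi_target, dtype=float))
    if len(pi_source) == 0 or len(pi_target) == 0:
        raise ValidationError("both centers must be non-empty")
    ds = np.clip(np.asarray(d_adv(pi_source), dtype=float).ravel(),
                 EPS, 1 - EPS)
    dt = np.clip(np.asarray(d_adv(pi_target), dtype=float).ravel(),
                 EPS, 1 - EPS)
    return float(-np.mean(np.log(ds)) - np.mean(np.log(1.0 - dt)))


def classifier_loss(c, pi_batch: np.ndarray, labels) -> float:
    """Cross-entropy -E[log C_y(π(x))] over a labelled source batch."""
    pi_batch = np.atleast_2d(np.asarray(pi_batch, dtype=float))
    labels = np.asarray(labels, dtype=int)
    probs = np.clip(np.atleast_2d(np.asarray(c(pi_batch), dtype=float)),
                    EPS, 1 - EPS)
    K = probs.shape[1]
    if labels.min() < 0 or labels.max() >= K:
        raise ValidationError(
            f"labels must lie in 0..{K - 1}, got range "
            f"[{labels.min()}, {labels.max()}]")
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels])))


def joint_objective(l_cls: float, l_adv: float, l_rec: float,
                    lam1: float, lam2: float) -> float:
    """L = L_cls + λ1 L_adv + λ2 L_rec."""
    if lam1 < 0 or lam2 < 0:
        raise ConfigError("λ1 and λ2 must be non-negative")
    return float(l_cls + lam1 * l_adv + lam2 * l_rec)


# ---------------------------------------------------------------------
# parameters and the shared forward pass
# ---------------------------------------------------------------------

REP_PARAMS = ("W_p1", "b_p1", "W_k1", "b_k1", "W_k2", "b_k2",
              "U_p1", "U_k1")
CLS_PARAMS = ("C_W1", "C_b1", "C_W2", "C_b2")
DISC_PARAMS = ("D_W1", "D_b1", "D_W2", "D_b2")


def _init_params(p: int, d_k: int, d_z: int, hidden: int, K: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    def w(rows, cols):
        return rng.normal(0.0, 1.0 / np.sqrt(max(cols, 1)), (rows, cols))

    return {
        "W_p1": w(d_z, p), "b_p1": np.zeros(d_z),
        "W_k1": w(d_z, d_k), "b_k1": np.zeros(d_z),
        "W_k2": w(d_k, d_z), "b_k2": np.zeros(d_k),
        "U_p1": w(d_z, d_z), "U_k1": w(d_z, d_z),
        "C_W1": w(hidden, 2 * d_z), "C_b1": np.zeros(hidden),
        "C_W2": w(K, hidden), "C_b2": np.zeros(K),
        "D_W1": w(hidden, 2 * d_z), "D_b1": np.zeros(hidden),
        "D_W2": w(1, hidden), "D_b2": np.zeros(1),
    }


def _representation(params: dict, Xp: Tensor, Xk: Tensor) -> dict:
    """Batch forward through encoders, decoder and co-attention.

    Row/column means of the per-sample correlation matrix
    M = z^p (z^k)^T reduce to z^p · mean(z^k) and z^k · mean(z^p), which
    is what is computed here (verified against the explicit outer-product
    route in the tests).
    """
    Zp = Xp @ params["W_p1"].T + params["b_p1"]
    Zk = Xk @ params["W_k1"].T + params["b_k1"]
    Xk_hat = Zk @ params["W_k2"].T + params["b_k2"]
    alpha_p = (Zp * Zk.mean(axis=1, keepdims=True)).softmax(axis=1)
    alpha_k = (Zk * Zp.mean(axis=1, keepdims=True)).softmax(axis=1)
    Bp = ((Zp + alpha_p * Zk) @ params["U_p1"].T).tanh()
    Bk = ((Zk + alpha_k * Zp) @ params["U_k1"].T).tanh()
    Pi = concat([Bp * Zp, Bk * Zk], axis=1)
    return {"Zp": Zp, "Zk": Zk, "Xk_hat": Xk_hat, "alpha_p": alpha_p,
            "alpha_k": alpha_k, "Bp": Bp, "Bk": Bk, "Pi": Pi}


def _classify(params: dict, Pi: Tensor) -> Tensor:
    H = (Pi @ params["C_W1"].T + params["C_b1"]).tanh()
    return (H @ params["C_W2"].T + params["C_b2"]).softmax(axis=1)


def _discriminate(params: dict, Pi: Tensor) -> Tensor:
    H = (Pi @ params["D_W1"].T + params["D_b1"]).tanh()
    return (H @ params["D_W2"].T + params["D_b2"]).sigmoid()


def _cross_entropy(probs: Tensor, labels: np.ndarray) -> Tensor:
    onehot = np.zeros(probs.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    logp = probs.clip(EPS, 1 - EPS).log()
    return -(Tensor(onehot) * logp).sum(axis=1).mean()


@dataclass
class ModelState:
    """Trained parameter set Θ plus the dimensions needed to rebuild the
    forward pass."""
    params: dict[str, np.ndarray]
    p: int
    d_k: int
    d_z: int
    hidden: int
    K: int

    def _tensors(self) -> dict[str, Tensor]:
        return {k: Tensor(v) for k, v in self.params.items()}

    def representation(self, Xp, Xk) -> np.ndarray:
        out = _representation(self._tensors(),
                              Tensor(np.atleast_2d(Xp)),
                              Tensor(np.atleast_2d(Xk)))
        return out["Pi"].value

    def predict_proba(self, Xp, Xk) -> np.ndarray:
        pi = self.representation(Xp, Xk)
        return _classify(self._tensors(), Tensor(pi)).value

    def discriminator_proba(self, Xp, Xk) -> np.ndarray:
        pi = self.representation(Xp, Xk)
        return _discriminate(self._tensors(), Tensor(pi)).value.ravel()

    def to_json(self) -> str:
        return json.dumps({
            "format": "sepsaki-risk-model", "version": 1,
            "p": self.p, "d_k": self.d_k, "d_z": self.d_z,
            "hidden": self.hidden, "K": self.K,
            "params": {k: v.tolist() for k, v in self.params.items()},
        })

    def save(self, path) -> None:
        atomic_write_text(path, self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "ModelState":
        d = json.loads(text)
        if d.get("format") != "sepsaki-risk-model":
            raise ValidationError("not a sepsaki risk-model file")
        return cls(params={k: np.array(v) for k, v in d["params"].items()},
                   p=d["p"], d_k=d["d_k"], d_z=d["d_z"],
                   hidden=d["hidden"], K=d["K"])

    @classmethod
    def load(cls, path) -> "ModelState":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------

class AKIRiskModel:
    """Knowledge-aware adversarial risk model over a two-center cohort.

    Parameters
    ----------
    source_xp, source_xk, source_y :
        Labelled source-center clinical features (n_s, p), knowledge
        features (n_s, d_k) and outcome labels in {0, ..., K-1}.
    target_xp, target_xk :
        Unlabelled target-center features.
    d_z, hidden, K :
        Latent dimension, head hidden width, number of outcome classes.

    Examples
    --------
    >>> model = AKIRiskModel(Xs, Ks, ys, Xt, Kt)      # doctest: +SKIP
    >>> res = model.fit(lam1=0.1, lam2=0.1, seed=0)   # doctest: +SKIP
    >>> print(res.summary())                          # doctest: +SKIP
    """

    def __init__(self, source_xp, source_xk, source_y,
                 target_xp, target_xk,
                 d_z: int = 16, hidden: int = 16, K: int = 2):
        self.source_xp = np.atleast_2d(np.asarray(source_xp, dtype=float))
        self.source_xk = np.atleast_2d(np.asarray(source_xk, dtype=float))
        self.source_y = np.asarray(source_y, dtype=int)
        self.target_xp = np.atleast_2d(np.asarray(target_xp, dtype=float))
        self.target_xk = np.atleast_2d(np.asarray(target_xk, dtype=float))
        if len(self.source_xp) == 0 or len(self.target_xp) == 0:
            raise ValidationError("both centers must be non-empty")
        if len(self.source_xp) != len(self.source_y):
            raise ValidationError("source features and labels disagree")
        if self.source_xp.shape[1] != self.target_xp.shape[1]:
            raise ValidationError("centers have different feature dims")
        if self.source_xk.shape[1] != self.target_xk.shape[1]:
            raise ValidationError(
                "centers have different knowledge feature dims")
        if self.source_y.min() < 0 or self.source_y.max() >= K:
            raise ValidationError(f"labels must lie in 0..{K - 1}")
        self.d_z, self.hidden, self.K = d_z, hidden, K

    @classmethod
    def from_dataframes(cls, source: pd.DataFrame, target: pd.DataFrame,
                        label_col: str = "label",
                        feature_prefix: str = "x",
                        knowledge_prefix: str = "k",
                        **kwargs) -> "AKIRiskModel":
        """Build from feature tables whose clinical columns start with
        `feature_prefix` and knowledge columns with `knowledge_prefix`."""
        fcols = [c for c in source.columns if c.startswith(feature_prefix)
                 and c != label_col]
        kcols = [c for c in source.columns if c.startswith(knowledge_prefix)]
        if not fcols:
            raise ValidationError(
                f"no feature columns with prefix {feature_prefix!r}")
        if not kcols:
            raise ValidationError(
                f"no knowledge columns with prefix {knowledge_prefix!r}")
        return cls(source[fcols].to_numpy(float),
                   source[kcols].to_numpy(float),
                   source[label_col].to_numpy(int),
                   target[fcols].to_numpy(float),
                   target[kcols].to_numpy(float), **kwargs)

    def fit(self, lam1: float = 0.1, lam2: float = 0.1,
            learning_rate: float = 0.2, epochs: int = 300, seed: int = 0,
            scheme: str = "gradient-reversal") -> "AKIRiskResults":
        """Minimise L_cls + λ1 L_adv + λ2 L_rec by full-batch SGD.

        With `scheme="gradient-reversal"` (default) a single optimiser
        runs; the representation receives the negated, λ1-scaled
        discriminator gradient.  With `scheme="alternating"` the
        discriminator and the representation+classifier take turns.
        Deterministic given `seed`.
        """
        if lam1 < 0 or lam2 < 0:
            raise ConfigError("λ1 and λ2 must be non-negative")
        if scheme not in ("gradient-reversal", "alternating"):
            raise ConfigError(
                f"unknown adversarial scheme {scheme!r}")
        rng = np.random.default_rng(child_seed(seed, "risk-init"))
        p = self.source_xp.shape[1]
        d_k = self.source_xk.shape[1]
        values = _init_params(p, d_k, self.d_z, self.hidden, self.K, rng)
        params = {k: Tensor(v, requires_grad=True)
                  for k, v in values.items()}
        Xp_s, Xk_s = Tensor(self.source_xp), Tensor(self.source_xk)
        Xp_t, Xk_t = Tensor(self.target_xp), Tensor(self.target_xk)
        y_s = self.source_y
        n_s, n_t = len(self.source_xp), len(self.target_xp)

        rep_cls = REP_PARAMS + CLS_PARAMS
        traces = {"cls": [], "adv": [], "rec": [], "total": []}
        for epoch in range(epochs):
            for t in params.values():
                t.grad = None
            rep_s = _representation(params, Xp_s, Xk_s)
            rep_t = _representation(params, Xp_t, Xk_t)
            diff = rep_s["Xk_hat"] - Xk_s
            l_rec = (diff * diff).sum(axis=1).mean()
            probs = _classify(params, rep_s["Pi"])
            l_cls = _cross_entropy(probs, y_s)

            if scheme == "gradient-reversal":
                # standard reversal: the discriminator minimises L_adv at
                # full strength while the representation receives the
                # lam1-scaled, sign-flipped gradient
                d_s = _discriminate(params,
                                    grad_reverse(rep_s["Pi"], lam1))
                d_t = _discriminate(params,
                                    grad_reverse(rep_t["Pi"], lam1))
                l_adv = (-(d_s.clip(EPS, 1 - EPS).log()).mean()
                         - ((1.0 - d_t).clip(EPS, 1 - EPS).log()).mean())
                total = l_cls + l_adv + lam2 * l_rec
                if not np.isfinite(total.value):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch}",
                        trace={k: np.array(v) for k, v in traces.items()})
                total.backward()
                for t in params.values():
                    if t.grad is not None:
                        t.value = t.value - learning_rate * t.grad
            else:  # alternating min–max
                # (a) discriminator step on frozen representations
                pi_s = Tensor(rep_s["Pi"].value)
                pi_t = Tensor(rep_t["Pi"].value)
                d_s = _discriminate(params, pi_s)
                d_t = _discriminate(params, pi_t)
                l_adv = (-(d_s.clip(EPS, 1 - EPS).log()).mean()
                         - ((1.0 - d_t).clip(EPS, 1 - EPS).log()).mean())
                l_adv.backward()
                for name in DISC_PARAMS:
                    t = params[name]
                    if t.grad is not None:
                        t.value = t.value - learning_rate * t.grad
                        t.grad = None
                # (b) representation + classifier step; discriminator
                # frozen, its loss entering with reversed sign
                frozen = {k: (Tensor(v.value) if k in DISC_PARAMS else v)
                          for k, v in params.items()}
                d_s2 = _discriminate(frozen, rep_s["Pi"])
                d_t2 = _discriminate(frozen, rep_t["Pi"])
                l_adv_rep = (-(d_s2.clip(EPS, 1 - EPS).log()).mean()
                             - ((1.0 - d_t2).clip(EPS, 1 - EPS)
                                .log()).mean())
                total = l_cls + lam2 * l_rec - lam1 * l_adv_rep
                if not np.isfinite(total.value):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch}",
                        trace={k: np.array(v) for k, v in traces.items()})
                total.backward()
                for name in rep_cls:
                    t = params[name]
                    if t.grad is not None:
                        t.value = t.value - learning_rate * t.grad

            traces["cls"].append(float(l_cls.value))
            traces["adv"].append(float(l_adv.value))
            traces["rec"].append(float(l_rec.value))
            traces["total"].append(joint_objective(
                float(l_cls.value), float(l_adv.value),
                float(l_rec.value), lam1, lam2))

        state = ModelState(params={k: t.value for k, t in params.items()},
                           p=p, d_k=d_k, d_z=self.d_z,
                           hidden=self.hidden, K=self.K)
        config = {"lam1": lam1, "lam2": lam2,
                  "learning_rate": learning_rate, "epochs": epochs,
                  "seed": seed, "scheme": scheme, "d_z": self.d_z,
                  "hidden": self.hidden, "K": self.K,
                  "n_source": n_s, "n_target": n_t}
        return AKIRiskResults(
            state=state,
            traces={k: np.array(v) for k, v in traces.items()},
            config=config)


@dataclass
class AKIRiskResults:
    """Fit results: trained parameters, loss traces and prediction
    methods."""
    state: ModelState
    traces: dict[str, np.ndarray]
    config: dict

    def predict_proba(self, Xp, Xk) -> np.ndarray:
        """K-way outcome probabilities, rows summing to one."""
        if self.state is None:
            raise NotFittedError("model has no trained state")
        return self.state.predict_proba(Xp, Xk)

    def predict_risk(self, sample_or_xp, xk=None) -> np.ndarray:
        """Risk for one `PatientSample` (or an (Xp, Xk) pair).  For K=2
        the positive-class column is the AKI risk."""
        if isinstance(sample_or_xp, PatientSample):
            probs = self.predict_proba(sample_or_xp.x_p[None, :],
                                       sample_or_xp.x_k[None, :])
            return probs[0]
        return self.predict_proba(sample_or_xp, xk)

    def discriminator_proba(self, Xp, Xk) -> np.ndarray:
        """Discriminator's probability that each sample is source-center."""
        return self.state.discriminator_proba(Xp, Xk)

    def summary(self) -> str:
        c = self.config
        lines = [
            "Knowledge-aware adversarial AKI risk model",
            "=" * 58,
            f"{'n (source / target)':<28}{c['n_source']} / {c['n_target']}",
            f"{'feature dims (p / d_k)':<28}"
            f"{self.state.p} / {self.state.d_k}",
            f"{'latent dim d_z':<28}{self.state.d_z}",
            f"{'outcome classes K':<28}{self.state.K}",
            f"{'adversarial scheme':<28}{c['scheme']}",
            f"{'lambda1 / lambda2':<28}{c['lam1']} / {c['lam2']}",
            f"{'epochs / learning rate':<28}"
            f"{c['epochs']} / {c['learning_rate']}",
            "-" * 58,
            f"{'final classifier loss':<28}{self.traces['cls'][-1]:.6f}",
            f"{'final adversarial loss':<28}{self.traces['adv'][-1]:.6f}",
            f"{'final reconstruction loss':<28}{self.traces['rec'][-1]:.6f}",
            f"{'final joint objective':<28}{self.traces['total'][-1]:.6f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        payload = json.loads(self.state.to_json())
        payload["config"] = self.config
        payload["traces"] = {k: v.tolist() for k, v in self.traces.items()}
        atomic_write_text(path, json.dumps(payload))

    @classmethod
    def load(cls, path) -> "AKIRiskResults":
        text = Path(path).read_text(encoding="utf-8")
        d = json.loads(text)
        state = ModelState.from_json(text)
        return cls(state=state,
                   traces={k: np.array(v)
                           for k, v in d.get("traces", {}).items()},
                   config=d.get("config", {}))
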