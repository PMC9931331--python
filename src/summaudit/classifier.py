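"""Multitask segment classifier: subjectivity (3), clinical role (9), probable (2).

A frozen feature extractor turns a segment string into a fixed vector; a
trainable linear-tanh tail (the only "encoder" parameters that learn) feeds
three per-task perceptron heads.  The training objective is the weighted sum
of the three per-task mean cross-entropies,

    L_all = lambda_sub * L_sub + lambda_role * L_role + lambda_prob * L_prob,

with the weights normalized to sum to one.  Optimization is Adam with the
reference protocol (20 epochs, lr 1e-5, batch 32, held-out dev/test splits
of 300 drawn by seeded sampling, results averaged over 3 seeds).

Everything is plain NumPy float64, so runs are deterministic given a seed.
The default encoder is a hashed bag-of-tokens projection; any object
satisfying :class:`EncoderContract` (e.g. a pretrained transformer wrapper)
can be substituted.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Protocol, Sequence

import numpy as np

from .corpus import ClinicalRole, LabelSet, Segment, Subjectivity

__all__ = [
    "TaskWeights",
    "LossBreakdown",
    "TrainConfig",
    "EncoderContract",
    "HashedTextEncoder",
    "ModelState",
    "TASKS",
    "TASK_CLASSES",
    "enumerate_grid_weights",
    "compute_loss",
    "train",
    "predict",
    "predict_labelsets",
    "grid_search",
]

TASKS = ("sub", "role", "prob")

SUB_CLASSES: tuple[Subjectivity, ...] = (
    Subjectivity.LOW,
    Subjectivity.MIDDLE,
    Subjectivity.HIGH,
)
ROLE_CLASSES: tuple[ClinicalRole, ...] = tuple(ClinicalRole)
PROB_CLASSES: tuple[bool, ...] = (False, True)

TASK_CLASSES: Mapping[str, int] = {"sub": 3, "role": 9, "prob": 2}


@dataclass(frozen=True)
class TaskWeights:
    """Per-task loss weights; must be nonnegative and sum to 1."""

    lambda_sub: float
    lambda_role: float
    lambda_prob: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(v < 0 for v in vals):
            raise ValueError("task weights must be nonnegative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("task weights must sum to 1 (within 1e-9)")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lambda_sub, self.lambda_role, self.lambda_prob)

    @classmethod
    def normalized(cls, sub: float, role: float, prob: float) -> "TaskWeights":
        total = sub + role + prob
        if total <= 0:
            raise ValueError("at least one weight must be positive")
        return cls(sub / total, role / total, prob / total)

    @classmethod
    def uniform(cls) -> "TaskWeights":
        return cls(1 / 3, 1 / 3, 1 / 3)


def enumerate_grid_weights(step: float = 0.25) -> list[TaskWeights]:
    """The 16 grid-search settings: quarter-step simplex points plus uniform.

    Every nonnegative triple of multiples of ``step`` summing to 1 (15 for
    step 0.25), with the uniform (1/3, 1/3, 1/3) setting appended.
    """
    k = round(1.0 / step)
    out: list[TaskWeights] = []
    for a in range(k, -1, -1):
        for b in range(k - a, -1, -1):
            c = k - a - b
            out.append(TaskWeights(a * step, b * step, c * step))
    out.append(TaskWeights.uniform())
    return out


@dataclass(frozen=True)
class LossBreakdown:
    """Per-task mean cross-entropies and their weighted sum."""

    L_sub: float
    L_role: float
    L_prob: float
    L_all: float

    def to_dict(self) -> dict:
        return {
            "L_sub": self.L_sub,
            "L_role": self.L_role,
            "L_prob": self.L_prob,
            "L_all": self.L_all,
        }


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters (defaults follow the reference setup)."""

    epochs: int = 20
    learning_rate: float = 1e-5
    batch_size: int = 32
    n_heldout: int = 300
    n_seeds: int = 3
    seed: int = 0
    #: number of weight layers in each per-task perceptron head
    head_hidden_layers: int = 3
    #: fixed multiplier on head logits; architectural constant that keeps the
    #: conservative learning rate effective at this model scale
    logit_scale: float = 800.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.n_seeds) < 0:
            raise ValueError("config values must be nonnegative")
        if self.learning_rate <= 0 or self.head_hidden_layers < 1:
            raise ValueError("invalid training configuration")


class EncoderContract(Protocol):
    """Frozen featurizer plus a trainable tail interface."""

    out_dim: int

    def featurize(self, texts: Sequence[str]) -> np.ndarray: ...

    def init_tail(self, rng: np.random.Generator) -> dict: ...

    def encode(self, tail: Mapping[str, np.ndarray], X: np.ndarray) -> np.ndarray: ...


def _stable_hash(s: str) -> int:
    return zlib.crc32(s.encode("utf-8"))


class HashedTextEncoder:
    """Deterministic hashed bag-of-tokens encoder with a trainable tanh tail.

    The frozen body hashes whitespace tokens (and optionally character
    n-grams, for unspaced scripts) into a fixed-width count vector, L2
    normalized.  The trainable tail is one linear layer with tanh; it is the
    analogue of fine-tuning only an encoder's final layer.
    """

    name = "hashed"

    def __init__(
        self,
        n_features: int = 1024,
        out_dim: int = 128,
        char_ngram: Optional[int] = None,
    ):
        self.n_features = n_features
        self.out_dim = out_dim
        self.char_ngram = char_ngram

    def _features_one(self, text: str) -> np.ndarray:
        vec = np.zeros(self.n_features)
        for tok in text.split():
            vec[_stable_hash("w:" + tok) % self.n_features] += 1.0
        if self.char_ngram:
            n = self.char_ngram
            flat = text.replace(" ", "")
            for i in range(max(0, len(flat) - n + 1)):
                vec[_stable_hash("c:" + flat[i : i + n]) % self.n_features] += 1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def featurize(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack([self._features_one(t) for t in texts]) if len(texts) else np.zeros((0, self.n_features))

    def init_tail(self, rng: np.random.Generator) -> dict:
        scale = 1.0 / np.sqrt(self.n_features)
        return {
            "W": rng.normal(0.0, scale, size=(self.out_dim, self.n_features)),
            "b": np.zeros(self.out_dim),
        }

    def encode(self, tail: Mapping[str, np.ndarray], X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ tail["W"].T + tail["b"])


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def _mean_ce(scores: np.ndarray, gold: np.ndarray) -> float:
    logp = _log_softmax(np.asarray(scores, dtype=float))
    return float(-logp[np.arange(len(gold)), gold].mean())


def compute_loss(
    head_outputs: Mapping[str, np.ndarray],
    gold: Mapping[str, np.ndarray],
    w: TaskWeights,
) -> LossBreakdown:
    """Per-task mean cross-entropy and the weighted-sum overall loss.

    ``head_outputs[task]`` are raw class scores of shape (batch, classes) with
    class counts (3, 9, 2); ``gold[task]`` are integer class indices.
    """
    losses = {}
    for task in TASKS:
        scores = np.asarray(head_outputs[task], dtype=float)
        y = np.asarray(gold[task], dtype=int)
        if scores.ndim != 2 or scores.shape[1] != TASK_CLASSES[task]:
            raise ValueError(
                f"task {task!r}: expected (batch, {TASK_CLASSES[task]}) scores, "
                f"got {scores.shape}"
            )
        if scores.shape[0] != y.shape[0]:
            raise ValueError(f"task {task!r}: scores and gold are misaligned")
        losses[task] = _mean_ce(scores, y)
    lam = w.as_tuple()
    l_all = lam[0] * losses["sub"] + lam[1] * losses["role"] + lam[2] * losses["prob"]
    return LossBreakdown(losses["sub"], losses["role"], losses["prob"], l_all)


# ---------------------------------------------------------------------------
# model state and forward/backward
# ---------------------------------------------------------------------------


@dataclass
class ModelState:
    """Trained parameters plus provenance of the run."""

    weights: TaskWeights
    config: TrainConfig
    tail: dict
    heads: dict  # task -> list of {"W": ..., "b": ...}
    loss_trace: list[LossBreakdown] = field(default_factory=list)
    train_idx: list[int] = field(default_factory=list)
    dev_idx: list[int] = field(default_factory=list)
    test_idx: list[int] = field(default_factory=list)
    encoder_name: str = "hashed"

    def to_json(self, path: str | Path) -> None:
        def arr(a):
            return np.asarray(a).tolist()

        payload = {
            "weights": list(self.weights.as_tuple()),
            "config": {
                "epochs": self.config.epochs,
                "learning_rate": self.config.learning_rate,
                "batch_size": self.config.batch_size,
                "n_heldout": self.config.n_heldout,
                "n_seeds": self.config.n_seeds,
                "seed": self.config.seed,
                "head_hidden_layers": self.config.head_hidden_layers,
                "logit_scale": self.config.logit_scale,
            },
            "tail": {k: arr(v) for k, v in self.tail.items()},
            "heads": {
                t: [{"W": arr(l["W"]), "b": arr(l["b"])} for l in layers]
                for t, layers in self.heads.items()
            },
            "loss_trace": [lb.to_dict() for lb in self.loss_trace],
            "train_idx": self.train_idx,
            "dev_idx": self.dev_idx,
            "test_idx": self.test_idx,
            "encoder_name": self.encoder_name,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelState":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        w = TaskWeights(*d["weights"])
        cfg = TrainConfig(**d["config"])
        tail = {k: np.asarray(v) for k, v in d["tail"].items()}
        heads = {
            t: [{"W": np.asarray(l["W"]), "b": np.asarray(l["b"])} for l in layers]
            for t, layers in d["heads"].items()
        }
        trace = [LossBreakdown(**lb) for lb in d["loss_trace"]]
        return cls(
            weights=w,
            config=cfg,
            tail=tail,
            heads=heads,
            loss_trace=trace,
            train_idx=d["train_idx"],
            dev_idx=d["dev_idx"],
            test_idx=d["test_idx"],
            encoder_name=d["encoder_name"],
        )


def _init_heads(
    rng: np.random.Generator, in_dim: int, n_layers: int
) -> dict[str, list[dict]]:
    heads: dict[str, list[dict]] = {}
    for task in TASKS:
        layers: list[dict] = []
        for li in range(n_layers):
            out = TASK_CLASSES[task] if li == n_layers - 1 else in_dim
            if li == n_layers - 1:
                W = np.zeros((out, in_dim))  # zero-init output: logits start at 0
            else:
                W = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(out, in_dim))
            layers.append({"W": W, "b": np.zeros(out)})
        heads[task] = layers
    return heads


def _head_forward(
    layers: Sequence[Mapping[str, np.ndarray]], enc: np.ndarray, logit_scale: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    acts = [enc]
    a = enc
    for li, layer in enumerate(layers):
        z = a @ layer["W"].T + layer["b"]
        if li == len(layers) - 1:
            return logit_scale * z, acts
        a = np.tanh(z)
        acts.append(a)
    raise AssertionError("head has no layers")


def _head_backward(
    layers: Sequence[Mapping[str, np.ndarray]],
    acts: list[np.ndarray],
    g_logits: np.ndarray,
    logit_scale: float,
) -> tuple[list[dict], np.ndarray]:
    """Backprop one head; returns per-layer grads and grad wrt encoder output."""
    grads: list[dict] = [dict() for _ in layers]
    g = g_logits * logit_scale
    for li in range(len(layers) - 1, -1, -1):
        a_prev = acts[li]
        grads[li]["W"] = g.T @ a_prev
        grads[li]["b"] = g.sum(axis=0)
        g = g @ layers[li]["W"]
        if li > 0:
            g = g * (1.0 - a_prev**2)  # tanh'
    return grads, g


class _Adam:
    def __init__(self, cfg: TrainConfig):
        self.lr = cfg.learning_rate
        self.b1 = cfg.adam_beta1
        self.b2 = cfg.adam_beta2
        self.eps = cfg.adam_eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g**2
            m_hat = self.m[key] / (1 - self.b1**self.t)
            v_hat = self.v[key] / (1 - self.b2**self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _flatten_params(tail: dict, heads: dict) -> dict[str, np.ndarray]:
    flat = {"tail/W": tail["W"], "tail/b": tail["b"]}
    for task, layers in heads.items():
        for li, layer in enumerate(layers):
            flat[f"{task}/{li}/W"] = layer["W"]
            flat[f"{task}/{li}/b"] = layer["b"]
    return flat


def gold_targets(segments: Sequence[Segment]) -> dict[str, np.ndarray]:
    """Integer class targets per task; probable promotes subjectivity to high."""
    subs, roles, probs = [], [], []
    for seg in segments:
        if seg.gold_labels is None:
            raise ValueError(f"segment {seg.segment_id!r} lacks gold labels")
        ls = seg.gold_labels
        subs.append(SUB_CLASSES.index(ls.effective_subjectivity))
        roles.append(ROLE_CLASSES.index(ls.role))
        probs.append(int(ls.probable))
    return {
        "sub": np.asarray(subs, dtype=int),
        "role": np.asarray(roles, dtype=int),
        "prob": np.asarray(probs, dtype=int),
    }


def split_dataset(
    n: int, n_heldout: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded train/dev/test split with ``n_heldout`` each for dev and test."""
    if 2 * n_heldout >= n:
        raise ValueError("dataset too small for the requested held-out sizes")
    perm = np.random.default_rng(seed).permutation(n)
    dev = perm[:n_heldout]
    test = perm[n_heldout : 2 * n_heldout]
    train_idx = perm[2 * n_heldout :]
    return train_idx, dev, test


def train(
    segments: Sequence[Segment],
    encoder: EncoderContract,
    w: TaskWeights,
    cfg: TrainConfig = TrainConfig(),
    train_seed: Optional[int] = None,
    features: Optional[np.ndarray] = None,
) -> ModelState:
    """Train the multitask model; deterministic given seeds and data.

    The dev/test split is drawn with ``cfg.seed``; initialization and batch
    shuffling use ``train_seed`` (defaulting to ``cfg.seed``) so repeated
    runs with different training seeds share one split.  Precomputed
    ``features`` may be passed to avoid re-featurizing across runs.
    """
    X = encoder.featurize([s.text for s in segments]) if features is None else features
    targets = gold_targets(segments)
    n = len(segments)
    train_idx, dev_idx, test_idx = split_dataset(n, cfg.n_heldout, cfg.seed)

    rng = np.random.default_rng(cfg.seed if train_seed is None else train_seed)
    tail = encoder.init_tail(rng)
    heads = _init_heads(rng, encoder.out_dim, cfg.head_hidden_layers)
    opt = _Adam(cfg)
    lam = dict(zip(TASKS, w.as_tuple()))
    trace: list[LossBreakdown] = []

    for _ in range(cfg.epochs):
        order = rng.permutation(train_idx)
        ep = {"sub": 0.0, "role": 0.0, "prob": 0.0, "all": 0.0}
        n_batches = 0
        for lo in range(0, len(order), cfg.batch_size):
            batch = order[lo : lo + cfg.batch_size]
            Xb = X[batch]
            pre = Xb @ tail["W"].T + tail["b"]
            enc = np.tanh(pre)
            g_enc = np.zeros_like(enc)
            grads: dict[str, np.ndarray] = {}
            losses: dict[str, float] = {}
            for task in TASKS:
                logits, acts = _head_forward(heads[task], enc, cfg.logit_scale)
                y = targets[task][batch]
                logp = _log_softmax(logits)
                losses[task] = float(-logp[np.arange(len(y)), y].mean())
                p = np.exp(logp)
                p[np.arange(len(y)), y] -= 1.0
                g_logits = lam[task] * p / len(y)
                head_grads, g_task = _head_backward(
                    heads[task], acts, g_logits, cfg.logit_scale
                )
                g_enc += g_task
                for li, hg in enumerate(head_grads):
                    grads[f"{task}/{li}/W"] = hg["W"]
                    grads[f"{task}/{li}/b"] = hg["b"]
            d = g_enc * (1.0 - enc**2)
            grads["tail/W"] = d.T @ Xb
            grads["tail/b"] = d.sum(axis=0)
            opt.step(_flatten_params(tail, heads), grads)
            l_all = sum(lam[t] * losses[t] for t in TASKS)
            for t in TASKS:
                ep[t] += losses[t]
            ep["all"] += l_all
            n_batches += 1
        if n_batches:
            trace.append(
                LossBreakdown(
                    ep["sub"] / n_batches,
                    ep["role"] / n_batches,
                    ep["prob"] / n_batches,
                    ep["all"] / n_batches,
                )
            )

    return ModelState(
        weights=w,
        config=cfg,
        tail=tail,
        heads=heads,
        loss_trace=trace,
        train_idx=[int(i) for i in train_idx],
        dev_idx=[int(i) for i in dev_idx],
        test_idx=[int(i) for i in test_idx],
        encoder_name=getattr(encoder, "name", "custom"),
    )


def predict(
    texts: Sequence[str],
    state: ModelState,
    encoder: EncoderContract,
    features: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """Arg-max class indices per task; deterministic for fixed parameters."""
    X = encoder.featurize(list(texts)) if features is None else features
    enc = encoder.encode(state.tail, X)
    out: dict[str, np.ndarray] = {}
    for task in TASKS:
        logits, _ = _head_forward(state.heads[task], enc, state.config.logit_scale)
        out[task] = logits.argmax(axis=1)
    return out


def predict_labelsets(
    texts: Sequence[str],
    state: ModelState,
    encoder: EncoderContract,
    features: Optional[np.ndarray] = None,
) -> list[LabelSet]:
    """Predictions as LabelSet objects (subjectivity, role, probable)."""
    idx = predict(texts, state, encoder, features=features)
    return [
        LabelSet(
            subjectivity=SUB_CLASSES[s],
            role=ROLE_CLASSES[r],
            probable=bool(PROB_CLASSES[p]),
        )
        for s, r, p in zip(idx["sub"], idx["role"], idx["prob"])
    ]


def _macro_f1(pred: np.ndarray, gold: np.ndarray) -> float:
    labels = sorted(set(gold.tolist()) | set(pred.tolist()))
    f1s = []
    for lab in labels:
        tp = int(((pred == lab) & (gold == lab)).sum())
        fp = int(((pred == lab) & (gold != lab)).sum())
        fn = int(((pred != lab) & (gold == lab)).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    return float(np.mean(f1s)) if f1s else 0.0


def grid_search(
    segments: Sequence[Segment],
    encoder: EncoderContract,
    cfg: TrainConfig = TrainConfig(),
    weights_list: Optional[Sequence[TaskWeights]] = None,
    eval_split: str = "dev",
):
    """Evaluate every weight setting of the quarter-step grid (plus uniform).

    Each setting is trained ``cfg.n_seeds`` times with different training
    seeds over a shared split, and the mean held-out macro-F1 per task is
    reported.  Returns a pandas DataFrame with one row per setting.
    """
    import pandas as pd

    settings = list(weights_list) if weights_list is not None else enumerate_grid_weights()
    X = encoder.featurize([s.text for s in segments])
    targets = gold_targets(segments)
    rows = []
    for w in settings:
        scores = {t: [] for t in TASKS}
        for i in range(cfg.n_seeds):
            state = train(
                segments, encoder, w, cfg, train_seed=cfg.seed + i, features=X
            )
            idx = np.asarray(state.dev_idx if eval_split == "dev" else state.test_idx)
            pred = predict([], state, encoder, features=X[idx])
            for t in TASKS:
                scores[t].append(_macro_f1(pred[t], targets[t][idx]))
        rows.append(
            {
                "lambda_sub": w.lambda_sub,
                "lambda_role": w.lambda_role,
                "lambda_prob": w.lambda_prob,
                "f1_sub": float(np.mean(scores["sub"])),
                "f1_role": float(np.mean(scores["role"])),
                "f1_prob": float(np.mean(scores["prob"])),
            }
        )
    return pd.DataFrame(rows)
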