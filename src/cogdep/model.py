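"""Joint post-level distortion classification and user-level depression detection.

The architecture follows the hierarchical multi-task design: a shared text
encoder maps each post to a vector ``h_t``; a feed-forward head with a
12-way softmax classifies the post's cognitive-distortion category; an LSTM
runs over the user's post sequence and additive attention with a learned
query collapses the LSTM outputs into a single user vector, from which a
feed-forward head predicts depression.  Both tasks are trained jointly on
the weighted loss ``l = w1*l1 + w2*l2`` where ``l1`` is the masked mean
cross-entropy over labeled posts and ``l2`` the mean cross-entropy over
labeled users; setting ``w1 = 0`` recovers the single-task ablation
baseline.

The attention weights and per-post distortion predictions are surfaced on
every user prediction — they are the model's explanation payload: the posts
the model attended to, and the distorted thinking it found in them.

All computation is NumPy with hand-written backpropagation (see
:mod:`cogdep._nn`); training is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import _nn
from .corpus import Post, UserRecord
from .encoder import TinyEncoder, TokenSequence, Vocabulary
from .taxonomy import N_CLASSES, DistortionCategory

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "PostPrediction",
    "UserPrediction",
    "MultiTaskModel",
    "PostClassifier",
    "TrainingError",
    "distortion_loss",
    "joint_loss",
    "explanation_report",
]


class TrainingError(RuntimeError):
    pass


class ModelConfig(BaseModel):
    d_h: int = 32
    lstm_hidden: int = 32
    lstm_bidirectional: bool = False
    attention_dim: int = 32
    dep_hidden: int = 16
    n_distortion_classes: int = N_CLASSES
    loss_weights: tuple[float, float] = (1.0, 1.0)
    max_posts_per_user: int = 128
    max_tokens: int = 64
    vocab_size: int = 5000
    learning_rate: float = 0.02
    epochs: int = 30
    batch_size: int = 8
    validation_fraction: float = 0.2
    early_stopping_patience: int = 10
    attend_over: str = "lstm"  # "lstm" (sequential flow) or "raw" (literal)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if self.n_distortion_classes != N_CLASSES:
            raise ValueError(f"output head is fixed at {N_CLASSES} classes")
        w1, w2 = self.loss_weights
        if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
            raise ValueError("loss weights must be non-negative, not both zero")
        if self.attend_over not in ("lstm", "raw"):
            raise ValueError("attend_over must be 'lstm' or 'raw'")
        return self


class PostPrediction(BaseModel):
    post_id: str
    distribution: list[float]
    category: DistortionCategory
    confidence: float

    @model_validator(mode="after")
    def _normalized(self) -> "PostPrediction":
        if abs(sum(self.distribution) - 1.0) > 1e-6 or min(self.distribution) < 0:
            raise ValueError("distribution must be a probability vector")
        return self


class UserPrediction(BaseModel):
    user_id: str
    depression_probability: float = Field(ge=0.0, le=1.0)
    attention_weights: list[float]
    post_predictions: list[PostPrediction]

    @model_validator(mode="after")
    def _normalized(self) -> "UserPrediction":
        if abs(sum(self.attention_weights) - 1.0) > 1e-6:
            raise ValueError("attention weights must sum to 1")
        if len(self.attention_weights) != len(self.post_predictions):
            raise ValueError("one attention weight per (possibly truncated) post")
        return self


# ---------------------------------------------------------------------------
# Loss functions (exposed standalone for closed-form checks)


def distortion_loss(
    probs: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> float:
    """Masked mean negative log-likelihood over labeled posts (``l1``).

    Posts where ``mask`` is False contribute exactly zero; an all-masked
    batch yields 0 with a logged warning.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        logger.warning("distortion_loss: no labeled posts in batch; l1 = 0")
        return 0.0
    lab = np.asarray(labels)[mask]
    p = np.asarray(probs)[mask, lab]
    return float(-np.log(np.clip(p, 1e-12, None)).mean())


def joint_loss(
    l1: float, l2: float, weights: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Weighted joint objective ``l = w1*l1 + w2*l2`` (defaults: plain sum)."""
    if not (math.isfinite(l1) and math.isfinite(l2)):
        raise TrainingError(f"non-finite loss components: l1={l1}, l2={l2}")
    return weights[0] * l1 + weights[1] * l2


# ---------------------------------------------------------------------------


def _label_index(p: Post) -> Optional[int]:
    return p.label.index if p.label is not None else None


class _PreppedUser:
    __slots__ = ("user_id", "seqs", "labels", "y", "posts")

    def __init__(self, user: UserRecord, enc: TinyEncoder, max_posts: int):
        posts = user.posts[-max_posts:]  # keep the most recent posts
        self.user_id = user.user_id
        self.posts = posts
        self.seqs = [enc.tokenize(p.text) for p in posts]
        self.labels = [_label_index(p) for p in posts]
        self.y = user.depression_label


class MultiTaskModel:
    """The hierarchical multi-task classifier.

    Construct via :meth:`fit` (which builds the vocabulary from the training
    corpus) or :meth:`load`.
    """

    def __init__(self, config: ModelConfig, encoder: TinyEncoder):
        self.config = config
        self.encoder = encoder
        rng = np.random.default_rng(config.seed + 17)
        d = config.d_h
        H = config.lstm_hidden
        s_dim = (2 * H if config.lstm_bidirectional else H)
        if config.attend_over == "raw":
            s_dim = d
        self._s_dim = s_dim
        sc = 1.0 / np.sqrt(d)
        self.params: dict[str, np.ndarray] = {"emb": encoder.E}
        self.params["W_post"] = rng.normal(0.0, sc, size=(d, N_CLASSES))
        self.params["b_post"] = np.zeros(N_CLASSES)
        for name, _ in self._lstm_names():
            p = _nn.init_lstm_params(d, H, rng)
            for k, v in p.items():
                self.params[f"{name}/{k}"] = v
        ap = _nn.init_attention_params(s_dim, config.attention_dim, rng)
        for k, v in ap.items():
            self.params[f"attn/{k}"] = v
        sh = 1.0 / np.sqrt(s_dim)
        self.params["W_u1"] = rng.normal(0.0, sh, size=(s_dim, config.dep_hidden))
        self.params["b_u1"] = np.zeros(config.dep_hidden)
        self.params["W_u2"] = rng.normal(
            0.0, 1.0 / np.sqrt(config.dep_hidden), size=(config.dep_hidden, 2)
        )
        self.params["b_u2"] = np.zeros(2)
        self.training_log: list[dict] = []

    def _lstm_names(self):
        names = [("lstm_f", False)]
        if self.config.lstm_bidirectional:
            names.append(("lstm_b", True))
        return names

    def _sub(self, prefix: str) -> dict:
        return {k.split("/", 1)[1]: v
                for k, v in self.params.items() if k.startswith(prefix + "/")}

    # -- forward pieces ----------------------------------------------------

    def encode_posts(self, seqs: Sequence[TokenSequence]) -> np.ndarray:
        return self.encoder.encode(seqs)

    def classify_distortion(self, H: np.ndarray) -> np.ndarray:
        """12-way softmax distribution for each post representation row."""
        return _nn.softmax(H @ self.params["W_post"] + self.params["b_post"])

    def aggregate_user(self, H: np.ndarray):
        """LSTM + additive attention; returns (user vector, weights, cache)."""
        if H.shape[0] == 0:
            raise ValueError("cannot aggregate an empty post sequence")
        caches: dict = {}
        if self.config.attend_over == "raw":
            S = H
        else:
            outs = []
            for name, reverse in self._lstm_names():
                X = H[::-1] if reverse else H
                hs, cache = _nn.lstm_forward(X, self._sub(name))
                caches[name] = cache
                outs.append(hs[::-1] if reverse else hs)
            S = np.concatenate(outs, axis=1) if len(outs) > 1 else outs[0]
        u, alpha, acache = _nn.attention_forward(S, self._sub("attn"))
        caches["attn"] = acache
        caches["S"] = S
        return u, alpha, caches

    def classify_depression(self, u: np.ndarray):
        """Probability that the user is depressed, via the FFN head."""
        z = np.tanh(u @ self.params["W_u1"] + self.params["b_u1"])
        q = _nn.softmax(z @ self.params["W_u2"] + self.params["b_u2"])
        return float(q[1]), q, z

    # -- training ----------------------------------------------------------

    @classmethod
    def fit(
        cls,
        users: Sequence[UserRecord],
        seed_posts: Sequence[Post] = (),
        config: Optional[ModelConfig] = None,
    ) -> "MultiTaskModel":
        """Train a model jointly on user depression labels and post labels."""
        config = config or ModelConfig()
        labeled_users = [u for u in users if u.depression_label is not None]
        if not labeled_users:
            raise TrainingError("no users with depression labels")
        texts = [p.text for u in users for p in u.posts]
        texts += [p.text for p in seed_posts]
        vocab = Vocabulary.build(texts, max_size=config.vocab_size)
        enc = TinyEncoder(vocab, dim=config.d_h, max_tokens=config.max_tokens,
                          seed=config.seed)
        model = cls(config, enc)
        model._train(labeled_users, list(seed_posts))
        return model

    def _forward_user(self, pu: "_PreppedUser"):
        H = self.encode_posts(pu.seqs)
        P = self.classify_distortion(H)
        u, alpha, caches = self.aggregate_user(H)
        d_prob, q, z = self.classify_depression(u)
        return {"H": H, "P": P, "u": u, "alpha": alpha, "caches": caches,
                "q": q, "z": z, "d_prob": d_prob}

    def _backward_user(self, pu, fw, scale1, scale2, grads):
        cfg = self.config
        H, P = fw["H"], fw["P"]
        T = H.shape[0]
        dH = np.zeros_like(H)
        # user-level head
        if pu.y is not None and scale2 > 0:
            q, z, u = fw["q"], fw["z"], fw["u"]
            dlog = q.copy()
            dlog[pu.y] -= 1.0
            dlog *= scale2
            grads["W_u2"] += np.outer(z, dlog)
            grads["b_u2"] += dlog
            dz = (dlog @ self.params["W_u2"].T) * (1.0 - z**2)
            grads["W_u1"] += np.outer(u, dz)
            grads["b_u1"] += dz
            du = dz @ self.params["W_u1"].T
            dS, ag = _nn.attention_backward(du, fw["caches"]["attn"])
            for k, v in ag.items():
                grads[f"attn/{k}"] += v
            if cfg.attend_over == "raw":
                dH += dS
            else:
                Hh = cfg.lstm_hidden
                for j, (name, reverse) in enumerate(self._lstm_names()):
                    dhs = dS[:, j * Hh : (j + 1) * Hh]
                    if reverse:
                        dhs = dhs[::-1]
                    dX, lg = _nn.lstm_backward(dhs, fw["caches"][name])
                    if reverse:
                        dX = dX[::-1]
                    dH += dX
                    for k, v in lg.items():
                        grads[f"{name}/{k}"] += v
        # post-level head (masked)
        if scale1 > 0:
            dL = np.zeros_like(P)
            any_lab = False
            for t in range(T):
                y = pu.labels[t]
                if y is not None:
                    dL[t] = P[t]
                    dL[t, y] -= 1.0
                    any_lab = True
            if any_lab:
                dL *= scale1
                grads["W_post"] += H.T @ dL
                grads["b_post"] += dL.sum(axis=0)
                dH += dL @ self.params["W_post"].T
        for t in range(T):
            if np.any(dH[t]):
                self.encoder.grad_update(pu.seqs[t], dH[t], grads["emb"])

    def _seed_pass(self, seqs, labels, scale1, grads):
        H = self.encoder.encode(seqs)
        P = self.classify_distortion(H)
        lab = np.asarray(labels)
        loss = float(-np.log(np.clip(P[np.arange(len(lab)), lab], 1e-12, None)).sum())
        if scale1 > 0:
            dL = P.copy()
            dL[np.arange(len(lab)), lab] -= 1.0
            dL *= scale1
            grads["W_post"] += H.T @ dL
            grads["b_post"] += dL.sum(axis=0)
            dH = dL @ self.params["W_post"].T
            for t, s in enumerate(seqs):
                self.encoder.grad_update(s, dH[t], grads["emb"])
        return loss

    def _train(self, users: list[UserRecord], seed_posts: list[Post]) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 31)
        prepped = [_PreppedUser(u, self.encoder, cfg.max_posts_per_user)
                   for u in users]
        # stratified train/validation split on depression label
        by_class: dict[int, list] = {0: [], 1: []}
        for pu in prepped:
            by_class[pu.y].append(pu)
        train, val = [], []
        for cls_users in by_class.values():
            idx = rng.permutation(len(cls_users))
            n_val = int(round(cfg.validation_fraction * len(cls_users)))
            n_val = min(n_val, max(0, len(cls_users) - 1))
            val.extend(cls_users[i] for i in idx[:n_val])
            train.extend(cls_users[i] for i in idx[n_val:])
        if not train:
            raise TrainingError("empty training split")

        seed_seqs = [self.encoder.tokenize(p.text) for p in seed_posts]
        seed_labels = [p.label.index for p in seed_posts]
        seed_order = rng.permutation(len(seed_posts)) if seed_posts else []
        seed_ptr = 0
        # spread the full seed corpus across each epoch's batches
        n_batches = max(1, -(-len(train) // cfg.batch_size))
        seed_chunk = min(1024, -(-len(seed_posts) // n_batches)) if seed_posts else 0

        opt = _nn.Adam(self.params, lr=cfg.learning_rate)
        w1, w2 = cfg.loss_weights
        best_score, best_vloss, best_params, patience = -np.inf, np.inf, None, 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train))
            ep_l1_num = ep_l1_den = 0.0
            ep_l2_num = ep_l2_den = 0.0
            for start in range(0, len(order), cfg.batch_size):
                batch = [train[i] for i in order[start : start + cfg.batch_size]]
                sseq, slab = [], []
                if seed_posts and w1 > 0:
                    for _ in range(min(seed_chunk, len(seed_posts))):
                        j = seed_order[seed_ptr % len(seed_posts)]
                        sseq.append(seed_seqs[j])
                        slab.append(seed_labels[j])
                        seed_ptr += 1
                n_lab = len(sseq) + sum(
                    1 for pu in batch for y in pu.labels if y is not None
                )
                scale1 = (w1 / n_lab) if (n_lab and w1 > 0) else 0.0
                scale2 = w2 / len(batch) if batch else 0.0
                grads = {k: np.zeros_like(v) for k, v in self.params.items()}
                l1_sum = l2_sum = 0.0
                for pu in batch:
                    fw = self._forward_user(pu)
                    lab_idx = [t for t, y in enumerate(pu.labels) if y is not None]
                    if lab_idx and w1 > 0:
                        p_true = [fw["P"][t, pu.labels[t]] for t in lab_idx]
                        l1_sum += float(
                            -np.log(np.clip(p_true, 1e-12, None)).sum()
                        )
                    l2_sum += float(-np.log(max(fw["q"][pu.y], 1e-12)))
                    self._backward_user(pu, fw, scale1, scale2, grads)
                if sseq:
                    l1_sum += self._seed_pass(sseq, slab, scale1, grads)
                opt.step(grads)
                if n_lab:
                    ep_l1_num += l1_sum
                    ep_l1_den += n_lab
                ep_l2_num += l2_sum
                ep_l2_den += len(batch)
            l1 = ep_l1_num / ep_l1_den if ep_l1_den else 0.0
            l2 = ep_l2_num / ep_l2_den if ep_l2_den else 0.0
            l = joint_loss(l1, l2, cfg.loss_weights)
            score, vloss = self._validation_score(val if val else train)
            self.training_log.append(
                {"epoch": epoch, "l1": l1, "l2": l2, "l": l,
                 "val_f1": score, "val_loss": vloss}
            )
            # checkpoint on validation joint loss (robust on small splits,
            # covers both tasks); stop on validation-F1 patience
            if vloss < best_vloss:
                best_vloss = vloss
                best_params = {k: v.copy() for k, v in self.params.items()}
            if score > best_score + 1e-9:
                best_score = score
                patience = 0
            else:
                patience += 1
                if patience >= cfg.early_stopping_patience:
                    break
        if best_params is not None:
            for k in self.params:
                self.params[k][...] = best_params[k]

    def _validation_score(self, val: list) -> tuple[float, float]:
        """(F1 score, joint validation loss) on the validation users.

        The loss is ``w1*l1 + w2*l2`` over validation users (and their
        labeled posts); when F1 is undefined the score falls back to
        accuracy - 1 so that any defined F1 dominates it.
        """
        w1, w2 = self.config.loss_weights
        gold, pred = [], []
        l2_sum = l1_sum = 0.0
        n_lab = 0
        for pu in val:
            fw = self._forward_user(pu)
            gold.append(pu.y)
            pred.append(int(fw["d_prob"] >= 0.5))
            l2_sum += float(-np.log(max(fw["q"][pu.y], 1e-12)))
            if w1 > 0:
                for t, y in enumerate(pu.labels):
                    if y is not None:
                        l1_sum += float(-np.log(max(fw["P"][t, y], 1e-12)))
                        n_lab += 1
        vloss = w2 * l2_sum / len(val) + (w1 * l1_sum / n_lab if n_lab else 0.0)
        tp = sum(1 for g, p in zip(gold, pred) if g == 1 and p == 1)
        fp = sum(1 for g, p in zip(gold, pred) if g == 0 and p == 1)
        fn = sum(1 for g, p in zip(gold, pred) if g == 1 and p == 0)
        if tp + fp == 0 or tp + fn == 0 or tp == 0:
            acc = sum(1 for g, p in zip(gold, pred) if g == p) / len(gold)
            return acc - 1.0, vloss
        prec = tp / (tp + fp)
        rec = tp / (tp + fn)
        return 2 * prec * rec / (prec + rec), vloss

    # -- inference ---------------------------------------------------------

    def predict(self, users: Sequence[UserRecord]) -> list[UserPrediction]:
        """Depression probability, attention weights and per-post labels."""
        out = []
        for user in users:
            pu = _PreppedUser(user, self.encoder, self.config.max_posts_per_user)
            fw = self._forward_user(pu)
            posts = [
                PostPrediction(
                    post_id=p.post_id,
                    distribution=[float(x) for x in fw["P"][t]],
                    category=DistortionCategory.from_index(int(fw["P"][t].argmax())),
                    confidence=float(fw["P"][t].max()),
                )
                for t, p in enumerate(pu.posts)
            ]
            out.append(
                UserPrediction(
                    user_id=user.user_id,
                    depression_probability=fw["d_prob"],
                    attention_weights=[float(a) for a in fw["alpha"]],
                    post_predictions=posts,
                )
            )
        return out

    def predict_posts_proba(self, texts: Sequence[str]) -> np.ndarray:
        seqs = [self.encoder.tokenize(t) for t in texts]
        return self.classify_distortion(self.encoder.encode(seqs))

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(
            json.dumps(self.config.model_dump(), indent=2)
        )
        (directory / "vocab.json").write_text(
            json.dumps(self.encoder.vocab.to_json_dict())
        )
        np.savez(directory / "weights.npz",
                 **{k.replace("/", "__"): v for k, v in self.params.items()})
        (directory / "training_log.json").write_text(
            json.dumps(self.training_log, indent=2)
        )
        return directory

    @classmethod
    def load(cls, directory) -> "MultiTaskModel":
        directory = Path(directory)
        config = ModelConfig(**json.loads((directory / "config.json").read_text()))
        vocab = Vocabulary.from_json_dict(
            json.loads((directory / "vocab.json").read_text())
        )
        enc = TinyEncoder(vocab, dim=config.d_h, max_tokens=config.max_tokens,
                          seed=config.seed)
        model = cls(config, enc)
        with np.load(directory / "weights.npz") as npz:
            for k in model.params:
                model.params[k][...] = npz[k.replace("/", "__")]
        log_path = directory / "training_log.json"
        if log_path.exists():
            model.training_log = json.loads(log_path.read_text())
        return model


class PostClassifier:
    """Post-level-only classifier (encoder + softmax head) for seed training.

    This is the classifier used by the semi-supervised corpus expansion: it
    is fitted on the small gold seed set, then assigns soft labels to an
    unlabeled pool.
    """

    def __init__(self, dim: int = 32, max_tokens: int = 64,
                 vocab_size: int = 5000, learning_rate: float = 0.05,
                 epochs: int = 40, batch_size: int = 64, seed: int = 0):
        self.dim = dim
        self.max_tokens = max_tokens
        self.vocab_size = vocab_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.encoder: Optional[TinyEncoder] = None
        self.W: Optional[np.ndarray] = None
        self.b: Optional[np.ndarray] = None

    @property
    def is_fitted(self) -> bool:
        return self.encoder is not None

    def fit(self, posts: Sequence[Post]) -> "PostClassifier":
        labeled = [p for p in posts if p.label is not None]
        if not labeled:
            raise TrainingError("no labeled posts to train on")
        vocab = Vocabulary.build([p.text for p in labeled], max_size=self.vocab_size)
        enc = TinyEncoder(vocab, dim=self.dim, max_tokens=self.max_tokens,
                          seed=self.seed)
        rng = np.random.default_rng(self.seed + 7)
        W = rng.normal(0.0, 1.0 / np.sqrt(self.dim), size=(self.dim, N_CLASSES))
        b = np.zeros(N_CLASSES)
        seqs = [enc.tokenize(p.text) for p in labeled]
        y = np.array([p.label.index for p in labeled])
        params = {"emb": enc.E, "W": W, "b": b}
        opt = _nn.Adam(params, lr=self.learning_rate)
        for _ in range(self.epochs):
            order = rng.permutation(len(labeled))
            for s in range(0, len(order), self.batch_size):
                idx = order[s : s + self.batch_size]
                H = enc.encode([seqs[i] for i in idx])
                P = _nn.softmax(H @ W + b)
                dL = P.copy()
                dL[np.arange(len(idx)), y[idx]] -= 1.0
                dL /= len(idx)
                grads = {
                    "W": H.T @ dL,
                    "b": dL.sum(axis=0),
                    "emb": np.zeros_like(enc.E),
                }
                dH = dL @ W.T
                for row, i in enumerate(idx):
                    enc.grad_update(seqs[i], dH[row], grads["emb"])
                opt.step(grads)
        self.encoder, self.W, self.b = enc, W, b
        return self

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        if not self.is_fitted:
            raise TrainingError("classifier is not fitted")
        seqs = [self.encoder.tokenize(t) for t in texts]
        H = self.encoder.encode(seqs)
        return _nn.softmax(H @ self.W + self.b)

    def predict(self, texts: Sequence[str]) -> list[DistortionCategory]:
        P = self.predict_proba(texts)
        # np.argmax already breaks ties toward the lowest category index
        return [DistortionCategory.from_index(int(i)) for i in P.argmax(axis=1)]


def explanation_report(
    users: Sequence[UserRecord],
    predictions: Sequence[UserPrediction],
    top_k: int = 5,
) -> str:
    """Markdown report of the top-k attended posts per user with labels.

    This is the human-facing explanation: for each user flagged by the
    model, the posts that drove the prediction and the distorted thought
    pattern detected in each.
    """
    by_id = {u.user_id: u for u in users}
    lines = ["# Explanation report", ""]
    for pred in predictions:
        user = by_id.get(pred.user_id)
        lines.append(f"## User {pred.user_id} — "
                     f"P(depression) = {pred.depression_probability:.3f}")
        order = np.argsort(pred.attention_weights)[::-1][:top_k]
        for rank, t in enumerate(order, 1):
            pp = pred.post_predictions[t]
            text = ""
            if user is not None:
                texts = {p.post_id: p.text for p in user.posts}
                text = texts.get(pp.post_id, "")
            lines.append(
                f"{rank}. [attn {pred.attention_weights[t]:.3f}] "
                f"({pp.category.display_name}, conf {pp.confidence:.2f}) {text}"
            )
        lines.append("")
    return "\n".join(lines)
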