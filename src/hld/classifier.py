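"""Elman RNN sequence classifier and evaluation protocol.

The recurrent network is the minimal Elman form: one tanh hidden layer
fed by the current code vector and the previous hidden state, and a
softmax readout per time step.  It is trained with full backpropagation
through time on per-recording sequences of fused segment code vectors,
with gradient clipping and early stopping on a training-loss plateau.
Everything is plain numpy so runs are bit-reproducible from the seed.

Evaluation follows the usual one-vs-rest convention for multi-class
accuracy / precision / recall / F1 (macro-averaged over classes), with
recording-level 10-fold cross-validation so that no recording
contributes segments to both the training and the test side of a fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class RNNConfig:
    hidden_size: int = 64
    epochs: int = 200
    lr: float = 0.01
    clip: float = 5.0
    seed: int = 0
    init_scale: float = 0.1
    patience: int = 20  # early stopping on training-loss plateau
    min_delta: float = 1e-5

    def validate(self) -> None:
        if min(self.hidden_size, self.epochs) < 1 or self.lr < 0:
            raise ValueError("hidden_size and epochs must be >= 1, lr >= 0")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be positive")


@dataclass
class RNNModel:
    W_xh: np.ndarray
    W_hh: np.ndarray
    b_h: np.ndarray
    W_hy: np.ndarray
    b_y: np.ndarray
    classes: list
    loss_trace: list = field(default_factory=list)

    @property
    def hidden_size(self) -> int:
        return self.W_hh.shape[0]

    def params(self) -> dict:
        return {
            "W_xh": self.W_xh, "W_hh": self.W_hh, "b_h": self.b_h,
            "W_hy": self.W_hy, "b_y": self.b_y,
        }


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward(model: RNNModel, X: np.ndarray):
    """Forward pass over one (T, d) sequence; returns hidden states and
    per-step class probabilities."""
    T = len(X)
    H = model.hidden_size
    hs = np.zeros((T + 1, H))
    ps = np.zeros((T, len(model.classes)))
    for t in range(T):
        hs[t + 1] = np.tanh(model.W_xh @ X[t] + model.W_hh @ hs[t] + model.b_h)
        ps[t] = _softmax(model.W_hy @ hs[t + 1] + model.b_y)
    return hs, ps


def sequence_loss_and_grads(model: RNNModel, X: np.ndarray, y_idx: np.ndarray):
    """Mean cross-entropy over the sequence and full-BPTT gradients."""
    T = len(X)
    hs, ps = _forward(model, X)
    eps = 1e-12
    loss = -np.log(ps[np.arange(T), y_idx] + eps).mean()
    grads = {k: np.zeros_like(v) for k, v in model.params().items()}
    dh_next = np.zeros(model.hidden_size)
    for t in reversed(range(T)):
        dz = ps[t].copy()
        dz[y_idx[t]] -= 1.0
        dz /= T
        grads["W_hy"] += np.outer(dz, hs[t + 1])
        grads["b_y"] += dz
        dh = model.W_hy.T @ dz + dh_next
        da = dh * (1.0 - hs[t + 1] ** 2)
        grads["W_xh"] += np.outer(da, X[t])
        grads["W_hh"] += np.outer(da, hs[t])
        grads["b_h"] += da
        dh_next = model.W_hh.T @ da
    return loss, grads


def rnn_init(input_dim: int, classes: list, cfg: RNNConfig) -> RNNModel:
    rng = np.random.default_rng(cfg.seed)
    H, L = cfg.hidden_size, len(classes)
    s = cfg.init_scale
    return RNNModel(
        W_xh=rng.normal(0, s, (H, input_dim)),
        W_hh=rng.normal(0, s, (H, H)),
        b_h=np.zeros(H),
        W_hy=rng.normal(0, s, (L, H)),
        b_y=np.zeros(L),
        classes=list(classes),
    )


def rnn_train(sequences: list, labels: list, cfg: RNNConfig) -> RNNModel:
    """Train on per-recording sequences.

    ``sequences[i]`` is a (T_i, d) array of code vectors;
    ``labels[i]`` is the length-T_i list of per-segment labels.
    """
    cfg.validate()
    if not sequences:
        raise ValueError("no training sequences")
    classes = sorted({lab for seq in labels for lab in seq})
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    d = sequences[0].shape[1]
    if any(s.shape[1] != d for s in sequences):
        raise ValueError("all code vectors must have the same length")
    cls_idx = {c: i for i, c in enumerate(classes)}
    y_seqs = [np.array([cls_idx[l] for l in seq]) for seq in labels]
    model = rnn_init(d, classes, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    best_loss, stale = np.inf, 0
    for _ in range(cfg.epochs):
        order = rng.permutation(len(sequences))
        total = 0.0
        for i in order:
            loss, grads = sequence_loss_and_grads(model, sequences[i], y_seqs[i])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss on sequence {i}; aborting training"
                )
            total += loss
            if cfg.lr > 0:
                for name, g in grads.items():
                    gn = np.linalg.norm(g)
                    if gn > cfg.clip:
                        g = g * (cfg.clip / gn)
                    p = getattr(model, name)
                    setattr(model, name, p - cfg.lr * g)
        epoch_loss = total / len(sequences)
        model.loss_trace.append(epoch_loss)
        if epoch_loss < best_loss - cfg.min_delta:
            best_loss, stale = epoch_loss, 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    return model


def rnn_predict(model: RNNModel, sequence: np.ndarray):
    """Per-step predicted labels and class probabilities."""
    X = np.atleast_2d(np.asarray(sequence, dtype=float))
    if X.shape[1] != model.W_xh.shape[1]:
        raise ValueError(
            f"input dim {X.shape[1]} does not match model {model.W_xh.shape[1]}"
        )
    _, ps = _forward(model, X)
    preds = [model.classes[i] for i in ps.argmax(axis=1)]
    return preds, ps


def numerical_gradient_check(
    input_dim: int = 4, T: int = 2, hidden: int = 3, n_classes: int = 2,
    seed: int = 0, eps: float = 1e-5,
) -> float:
    """Max relative error between BPTT and central-difference gradients
    on a tiny random instance."""
    rng = np.random.default_rng(seed)
    cfg = RNNConfig(hidden_size=hidden, seed=seed)
    model = rnn_init(input_dim, list(range(n_classes)), cfg)
    X = rng.normal(size=(T, input_dim))
    y = rng.integers(n_classes, size=T)
    _, grads = sequence_loss_and_grads(model, X, y)
    worst = 0.0
    for name, g in grads.items():
        p = getattr(model, name)
        num = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = sequence_loss_and_grads(model, X, y)
            p[idx] = orig - eps
            lm, _ = sequence_loss_and_grads(model, X, y)
            p[idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        denom = np.maximum(np.abs(g) + np.abs(num), 1e-8)
        worst = max(worst, float(np.max(np.abs(g - num) / denom)))
    return worst


# ------------------------------------------------------------ evaluation

@dataclass
class EvalReport:
    classes: list
    confusion: np.ndarray  # (L, L) counts, rows = truth
    accuracy: float
    precision: float
    recall: float
    f1: float
    fold_scores: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "fold_scores": self.fold_scores,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(pred, truth, classes: list | None = None) -> EvalReport:
    """One-vs-rest TP/TN/FP/FN per class from the confusion matrix,
    macro-averaged accuracy, precision, recall and F1."""
    pred = list(pred)
    truth = list(truth)
    if not pred or len(pred) != len(truth):
        raise ValueError("need equal-length non-empty label lists")
    classes = sorted(set(truth) | set(pred)) if classes is None else list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    L = len(classes)
    conf = np.zeros((L, L), dtype=int)
    for t, p in zip(truth, pred):
        conf[idx[t], idx[p]] += 1
    n = conf.sum()
    accs, pres, recs, f1s = [], [], [], []
    for k in range(L):
        tp = conf[k, k]
        fn = conf[k].sum() - tp
        fp = conf[:, k].sum() - tp
        tn = n - tp - fn - fp
        accs.append((tp + tn) / n)
        pre = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        pres.append(pre)
        recs.append(rec)
        f1s.append(2 * pre * rec / (pre + rec) if pre + rec > 0 else 0.0)
    return EvalReport(
        classes=classes,
        confusion=conf,
        accuracy=float(np.mean(accs)),
        precision=float(np.mean(pres)),
        recall=float(np.mean(recs)),
        f1=float(np.mean(f1s)),
    )


def fold_assignment(n_items: int, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic partition of item indices into folds."""
    if n_items < folds:
        raise ValueError(f"need at least {folds} recordings for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    return [order[f::folds] for f in range(folds)]


def cross_validate(
    sequences: list, labels: list, cfg: RNNConfig, folds: int = 10, seed: int = 0,
) -> EvalReport:
    """Recording-level k-fold cross-validation with a pooled confusion
    matrix across folds."""
    assignment = fold_assignment(len(sequences), folds, seed)
    all_pred, all_true = [], []
    fold_scores = []
    for f, test_idx in enumerate(assignment):
        test_set = set(int(i) for i in test_idx)
        train_seqs = [s for i, s in enumerate(sequences) if i not in test_set]
        train_labs = [l for i, l in enumerate(labels) if i not in test_set]
        model = rnn_train(train_seqs, train_labs, cfg)
        fold_pred, fold_true = [], []
        for i in sorted(test_set):
            preds, _ = rnn_predict(model, sequences[i])
            fold_pred.extend(preds)
            fold_true.extend(labels[i])
        rep = evaluate(fold_pred, fold_true)
        fold_scores.append(rep.accuracy)
        all_pred.extend(fold_pred)
        all_true.extend(fold_true)
    report = evaluate(all_pred, all_true)
    report.fold_scores = fold_scores
    return report


def micro_accuracy(report: EvalReport) -> float:
    """Fraction of samples on the confusion diagonal."""
    return float(np.trace(report.confusion) / report.confusion.sum())
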