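"""Classifier arms: under-sampled train/test split, weighted cross-entropy,
a GRU recurrent classifier over the wavelet-domain feature sequence, and a
logistic clinical baseline.

The 513-entry radiomic vector is presented to the recurrent network as a
9-step sequence of 57 features (image domain first, then the 8 wavelet
sub-bands).  For the combined arm the clinical block is appended as a 10th
time step, zero-padded to 57.  Class imbalance is handled by under-sampling
the majority class into the training cohort and weighting the cross-entropy
loss; training uses Adam (default learning rate 1e-4, batch size 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._nn import Adam, sigmoid
from .errors import DataError, ShapeError

N_RADIOMIC = 513
N_PER_STEP = 57
N_STEPS = 9


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    n_pos_train: int
    n_neg_train: int
    n_pos_test: int
    n_neg_test: int
    seed: int


def build_split(labels: np.ndarray, n_pos_train: int, n_neg_train: int,
                seed: int) -> SplitPlan:
    """Under-sampling split: draw the requested positive/negative counts into
    the training cohort uniformly without replacement; everyone else tests."""
    labels = np.asarray(labels).astype(int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) < n_pos_train:
        raise DataError(f"need {n_pos_train} positives for training, cohort has {len(pos)}")
    if len(neg) < n_neg_train:
        raise DataError(f"need {n_neg_train} negatives for training, cohort has {len(neg)}")
    rng = np.random.default_rng(seed)
    train = np.concatenate([rng.choice(pos, size=n_pos_train, replace=False),
                            rng.choice(neg, size=n_neg_train, replace=False)])
    train = np.sort(train)
    test = np.setdiff1d(np.arange(len(labels)), train)
    return SplitPlan(
        train_idx=train, test_idx=test,
        n_pos_train=n_pos_train, n_neg_train=n_neg_train,
        n_pos_test=int(labels[test].sum()),
        n_neg_test=int(len(test) - labels[test].sum()),
        seed=seed,
    )


def weighted_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                           class_weights: tuple[float, float] = (1.0, 1.0),
                           eps: float = 1e-12) -> float:
    """Mean over samples of -weight(y) * log p(y) for binary labels.

    ``probs`` is the predicted probability of class 1; probabilities are
    clamped to [eps, 1-eps].  Unit weights recover standard cross-entropy.
    """
    p1 = np.clip(np.asarray(probs, dtype=float), eps, 1 - eps)
    y = np.asarray(labels).astype(int)
    w = np.where(y == 1, class_weights[1], class_weights[0])
    py = np.where(y == 1, p1, 1 - p1)
    return float(np.mean(-w * np.log(py)))


# ---------------------------------------------------------------------------
# GRU recurrent classifier
# ---------------------------------------------------------------------------

@dataclass
class RNNConfig:
    hidden_size: int = 64
    epochs: int = 200
    learning_rate: float = 1e-4
    batch_size: int = 10
    class_weights: tuple[float, float] | None = None  # None -> inverse train frequency
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 30

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.class_weights is not None and min(self.class_weights) <= 0:
            raise ValueError("class weights must be > 0")


def to_sequence(features: np.ndarray) -> np.ndarray:
    """Reshape (n, 513) or (n, 519) feature rows into (n, T, 57) sequences.

    513 columns -> 9 steps (image, LLL..HHH).  519 columns -> those 9 steps
    plus the 6-column clinical block zero-padded to 57 as a 10th step.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ShapeError(f"expected 2D feature array, got {X.shape}")
    n, p = X.shape
    if p == N_RADIOMIC:
        return X.reshape(n, N_STEPS, N_PER_STEP)
    if p > N_RADIOMIC and p - N_RADIOMIC <= N_PER_STEP:
        seq = np.zeros((n, N_STEPS + 1, N_PER_STEP))
        seq[:, :N_STEPS] = X[:, :N_RADIOMIC].reshape(n, N_STEPS, N_PER_STEP)
        seq[:, N_STEPS, :p - N_RADIOMIC] = X[:, N_RADIOMIC:]
        return seq
    raise ShapeError(f"feature count {p} is not 513 or 513+clinical(<=57)")


class _GRU:
    """Single-layer GRU; final hidden state -> affine -> 2-class softmax."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        def init(shape, fan_in):
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
        H = hidden
        self.Wz, self.Uz, self.bz = init((H, d_in), d_in), init((H, H), H), np.zeros(H)
        self.Wr, self.Ur, self.br = init((H, d_in), d_in), init((H, H), H), np.zeros(H)
        self.Wh, self.Uh, self.bh = init((H, d_in), d_in), init((H, H), H), np.zeros(H)
        self.Wo, self.bo = init((2, H), H), np.zeros(2)
        self._names = ["Wz", "Uz", "bz", "Wr", "Ur", "br", "Wh", "Uh", "bh", "Wo", "bo"]
        self.grads = {n: np.zeros_like(getattr(self, n)) for n in self._names}
        self.H = H

    @property
    def params(self):
        return [(getattr(self, n), self.grads[n]) for n in self._names]

    def forward(self, X: np.ndarray):
        """X: (B, T, D) -> logits (B, 2); caches per-step intermediates."""
        B, T, _D = X.shape
        h = np.zeros((B, self.H))
        cache = []
        for t in range(T):
            x = X[:, t]
            z = sigmoid(x @ self.Wz.T + h @ self.Uz.T + self.bz)
            r = sigmoid(x @ self.Wr.T + h @ self.Ur.T + self.br)
            rh = r * h
            c = np.tanh(x @ self.Wh.T + rh @ self.Uh.T + self.bh)
            h_new = (1 - z) * h + z * c
            cache.append((x, h, z, r, rh, c))
            h = h_new
        logits = h @ self.Wo.T + self.bo
        self._cache = (cache, h)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        cache, h_last = self._cache
        g = self.grads
        g["Wo"] += dlogits.T @ h_last
        g["bo"] += dlogits.sum(axis=0)
        dh = dlogits @ self.Wo
        for x, h_prev, z, r, rh, c in reversed(cache):
            dz = dh * (c - h_prev)
            dc = dh * z
            dh_prev = dh * (1 - z)
            da_c = dc * (1 - c ** 2)
            g["Wh"] += da_c.T @ x
            g["Uh"] += da_c.T @ rh
            g["bh"] += da_c.sum(axis=0)
            drh = da_c @ self.Uh
            dr = drh * h_prev
            dh_prev += drh * r
            da_z = dz * z * (1 - z)
            g["Wz"] += da_z.T @ x
            g["Uz"] += da_z.T @ h_prev
            g["bz"] += da_z.sum(axis=0)
            dh_prev += da_z @ self.Uz
            da_r = dr * r * (1 - r)
            g["Wr"] += da_r.T @ x
            g["Ur"] += da_r.T @ h_prev
            g["br"] += da_r.sum(axis=0)
            dh_prev += da_r @ self.Ur
            dh = dh_prev


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class RNNClassifier:
    net: _GRU
    config: RNNConfig
    mean: np.ndarray
    sd: np.ndarray
    history: dict = field(default_factory=dict)

    def predict(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        Xs = (X - self.mean) / self.sd
        seq = to_sequence(Xs)
        return _softmax(self.net.forward(seq))[:, 1]


def train_rnn(features: np.ndarray | pd.DataFrame, labels: np.ndarray,
              config: RNNConfig = RNNConfig()) -> RNNClassifier:
    """Train the GRU classifier on a (n, 513) or (n, 519) feature table.

    Features are standardized with training-set statistics only; the loss is
    class-weighted cross-entropy (default weights inverse to training class
    frequencies).  A small validation split drives early stopping; the best
    validation-loss parameters are restored.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    seq = to_sequence((X - mean) / sd)
    n = len(y)

    rng = np.random.default_rng(config.seed)
    net = _GRU(N_PER_STEP, config.hidden_size, rng)
    opt = Adam(net.params, lr=config.learning_rate)

    if config.class_weights is None:
        n1 = max(int(y.sum()), 1)
        n0 = max(n - n1, 1)
        cw = (n / (2.0 * n0), n / (2.0 * n1))
    else:
        cw = config.class_weights
    wvec = np.where(y == 1, cw[1], cw[0])

    # stratified validation split: proportional positives, so early stopping
    # is not driven by an all-negative (or near-empty) holdout
    pos = rng.permutation(np.flatnonzero(y == 1))
    neg = rng.permutation(np.flatnonzero(y == 0))
    k_pos = int(round(config.val_fraction * len(pos)))
    k_neg = int(round(config.val_fraction * len(neg)))
    val_idx = np.concatenate([pos[:k_pos], neg[:k_neg]])
    tr_idx = np.concatenate([pos[k_pos:], neg[k_neg:]])
    if k_pos < 2 or k_neg < 2 or len(pos) - k_pos == 0 or len(neg) - k_neg == 0:
        val_idx, tr_idx = np.array([], dtype=int), np.arange(n)

    def batch_loss_grad(idx):
        logits = net.forward(seq[idx])
        probs = _softmax(logits)
        onehot = np.eye(2)[y[idx]]
        w = wvec[idx]
        eps = 1e-12
        loss = float(np.mean(-w * np.log(probs[np.arange(len(idx)), y[idx]] + eps)))
        dlogits = w[:, None] * (probs - onehot) / len(idx)
        return loss, dlogits

    best = None
    best_val = np.inf
    bad = 0
    train_losses, val_losses = [], []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(tr_idx))
        ep_loss = 0.0
        for s in range(0, len(tr_idx), config.batch_size):
            idx = tr_idx[order[s:s + config.batch_size]]
            loss, dlogits = batch_loss_grad(idx)
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
        train_losses.append(ep_loss / len(tr_idx))
        if len(val_idx):
            logits = net.forward(seq[val_idx])
            probs = _softmax(logits)[:, 1]
            vl = weighted_cross_entropy(probs, y[val_idx], cw)
            val_losses.append(vl)
            if vl < best_val - 1e-6:
                best_val, bad = vl, 0
                best = [p.copy() for p, _ in net.params]
            else:
                bad += 1
                if bad >= config.patience:
                    break
    if best is not None:
        for (p, _), b in zip(net.params, best):
            p[...] = b
    clf = RNNClassifier(net=net, config=config, mean=mean, sd=sd)
    clf.history = {"train_loss": train_losses, "val_loss": val_losses}
    return clf


# ---------------------------------------------------------------------------
# clinical logistic baseline
# ---------------------------------------------------------------------------

@dataclass
class LogisticClassifier:
    model: LogisticRegression
    mean: np.ndarray
    sd: np.ndarray
    columns: list[str] | None = None

    @property
    def coef_(self) -> np.ndarray:
        return self.model.coef_[0] / self.sd  # on the original covariate scale

    @property
    def intercept_(self) -> float:
        return float(self.model.intercept_[0] - np.sum(self.model.coef_[0] * self.mean / self.sd))

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        Xa = np.asarray(X, dtype=float)
        return self.model.predict_proba((Xa - self.mean) / self.sd)[:, 1]


def train_clinical_logistic(covariates: np.ndarray | pd.DataFrame, labels: np.ndarray,
                            C: float = 1e4, seed: int = 0) -> LogisticClassifier:
    """Lightly L2-regularized logistic regression on clinical covariates.

    Covariates are standardized internally; coefficients are exposed on the
    original scale.  The (small) ridge keeps separation-prone fits finite.
    """
    X = np.asarray(covariates, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.isnan(X).any():
        raise DataError("clinical covariates contain missing values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    model = LogisticRegression(C=C, max_iter=10000, random_state=seed)
    model.fit((X - mean) / sd, y)
    cols = list(covariates.columns) if isinstance(covariates, pd.DataFrame) else None
    return LogisticClassifier(model=model, mean=mean, sd=sd, columns=cols)


def predict(classifier, features) -> np.ndarray:
    """Uniform inference entry point: probabilities in [0, 1] per subject."""
    return classifier.predict(features)
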