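"""A small class-weighted multi-layer perceptron.

Five ReLU hidden layers (10, 128, 256, 64, 16) and a softmax output,
trained full-batch with AdaDelta (initial rate 1.0) on class-weighted
categorical cross-entropy. A stratified validation split monitors the
loss: the learning-rate multiplier is reduced by a fixed fraction (0.8)
after two consecutive epochs without validation improvement, and the
best-validation parameters are restored after training. The output bias
starts at the log of the (weighted) class priors, so an uninformative
fit degrades gracefully to the prior-predicting solution. Inputs are
z-scored with statistics from the training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrainingError

__all__ = ["MLPClassifier"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MLPClassifier:
    hidden_layers: tuple[int, ...] = (10, 128, 256, 64, 16)
    learning_rate: float = 1.0
    rho: float = 0.95  # AdaDelta decay
    adadelta_eps: float = 1e-6
    plateau_factor: float = 0.8
    plateau_patience: int = 2
    epochs: int = 400
    validation_fraction: float = 0.15
    early_stopping_patience: int = 15  # epochs without validation improvement
    seed: int = 0

    classes_: np.ndarray = field(default=None, repr=False)
    _params: list = field(default=None, repr=False)
    _mu: np.ndarray = field(default=None, repr=False)
    _sd: np.ndarray = field(default=None, repr=False)

    def _init_params(self, n_in: int, n_out: int, rng: np.random.Generator) -> list:
        sizes = [n_in, *self.hidden_layers, n_out]
        params = []
        for li, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            if li == len(sizes) - 2:
                # zero-init output weights: the initial model is exactly the
                # prior predictor set through the output bias
                w = np.zeros((a, b))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
            params.append([w, np.zeros(b)])
        return params

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        acts = [x]
        h = x
        for i, (w, b) in enumerate(self._params):
            z = h @ w + b
            h = z if i == len(self._params) - 1 else np.maximum(z, 0.0)
            acts.append(h)
        return _softmax(acts[-1]), acts

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        class_weight: dict | None = None,
    ) -> "MLPClassifier":
        x = np.asarray(x, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise TrainingError("MLP training needs at least 2 classes")
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_to_idx[v] for v in y])
        n, n_out = len(x), len(self.classes_)

        self._mu = x.mean(axis=0)
        self._sd = x.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        xs = (x - self._mu) / self._sd

        sw_all = np.ones(n)
        if class_weight:
            sw_all = np.array([class_weight[c] for c in y], dtype=float)

        rng = np.random.default_rng(self.seed)
        self._params = self._init_params(x.shape[1], n_out, rng)

        # output bias at the log of the weighted class priors: with no
        # usable signal the best-validation model predicts by prior
        prior = np.bincount(yi, weights=sw_all, minlength=n_out)
        prior = prior / prior.sum()
        self._params[-1][1][:] = np.log(prior + 1e-12)

        tr_idx, val_idx = self._validation_split(yi, rng)
        monitor_val = val_idx is not None

        xs_tr, yi_tr, sw = xs[tr_idx], yi[tr_idx], sw_all[tr_idx]
        sw = sw / sw.sum()
        n_tr = len(tr_idx)
        onehot = np.zeros((n_tr, n_out))
        onehot[np.arange(n_tr), yi_tr] = 1.0

        eg = [[np.zeros_like(w), np.zeros_like(b)] for w, b in self._params]
        ex = [[np.zeros_like(w), np.zeros_like(b)] for w, b in self._params]

        def monitored_loss() -> float:
            if monitor_val:
                pv, _ = self._forward(xs[val_idx])
                wv = sw_all[val_idx] / sw_all[val_idx].sum()
                return float(
                    -(wv * np.log(pv[np.arange(len(val_idx)), yi[val_idx]] + 1e-12)).sum()
                )
            pt, _ = self._forward(xs_tr)
            return float(-(sw * np.log(pt[np.arange(n_tr), yi_tr] + 1e-12)).sum())

        lr = self.learning_rate
        best = monitored_loss()
        best_params = [[w.copy(), b.copy()] for w, b in self._params]
        stall = 0
        stop_stall = 0
        for _ in range(self.epochs):
            probs, acts = self._forward(xs_tr)
            delta = (probs - onehot) * sw[:, None]
            for li in range(len(self._params) - 1, -1, -1):
                w, b = self._params[li]
                grad_w = acts[li].T @ delta
                grad_b = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ w.T) * (acts[li] > 0)
                for pi, (param, grad) in enumerate(((w, grad_w), (b, grad_b))):
                    eg[li][pi] = self.rho * eg[li][pi] + (1 - self.rho) * grad**2
                    step = (
                        np.sqrt(ex[li][pi] + self.adadelta_eps)
                        / np.sqrt(eg[li][pi] + self.adadelta_eps)
                        * grad
                    )
                    ex[li][pi] = self.rho * ex[li][pi] + (1 - self.rho) * step**2
                    param -= lr * step

            loss = monitored_loss()
            if loss < best - 1e-9:
                best = loss
                best_params = [[w.copy(), b.copy()] for w, b in self._params]
                stall = 0
                stop_stall = 0
            else:
                stall += 1
                stop_stall += 1
                if stall >= self.plateau_patience:
                    lr *= self.plateau_factor
                    stall = 0
                if monitor_val and stop_stall >= self.early_stopping_patience:
                    break

        if monitor_val:  # keep the best-validation parameters
            self._params = best_params
        return self

    def _validation_split(self, yi: np.ndarray, rng: np.random.Generator):
        """Stratified validation indices; ``None`` when classes are too small."""
        if self.validation_fraction <= 0:
            return np.arange(len(yi)), None
        tr, val = [], []
        for cls in np.unique(yi):
            idx = np.flatnonzero(yi == cls)
            idx = rng.permutation(idx)
            n_val = int(round(self.validation_fraction * len(idx)))
            if len(idx) >= 4:
                n_val = max(n_val, 1)
            else:
                n_val = 0  # class too small to spare a sample
            val.extend(idx[:n_val])
            tr.extend(idx[n_val:])
        if len(val) < 2:
            return np.arange(len(yi)), None
        return np.sort(np.asarray(tr)), np.sort(np.asarray(val))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise TrainingError("model is not fitted")
        xs = (np.asarray(x, dtype=float) - self._mu) / self._sd
        probs, _ = self._forward(xs)
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(x), axis=1)]
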