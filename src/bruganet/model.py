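"""Dense neural-network classifier for fused ECG traces.

The architecture is fixed: three hidden blocks, each a fully connected
layer followed by additive Gaussian noise (train-time only), ReLU
activation and batch normalization, closed by a fully connected output
unit with sigmoid activation.  The sigmoid output ŷ ∈ (0, 1) is read as
the probability of a positive sodium-channel-blocker response.

Training minimizes binary cross-entropy with Adam, optional
inverse-frequency class weights, and early stopping on a stratified
10% held-out slice of the training split.  The implementation is
self-contained numpy (forward, backprop through batch normalization,
Adam) so inference, input gradients for saliency, and serialization are
all exact and dependency-free.

A 7-member fold ensemble (:class:`FoldEnsembleClassifier`) trains one
model per stratified cross-validation fold complement and scores a
patient by the mean (and spread) of the member sigmoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

__all__ = [
    "ModelConfig",
    "DenseNoiseClassifier",
    "FoldEnsembleClassifier",
    "build_model",
    "train_model",
    "predict_score",
    "ensemble_score",
    "save_model",
    "load_model",
]

_EPS_BN = 1e-5
_EPS_CLIP = 1e-7


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ModelConfig:
    """Declarative training configuration (maps onto the estimator)."""

    hidden_sizes: tuple[int, int, int] = (128, 128, 128)
    gaussian_noise_sd: float = 0.05
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    early_stop_patience: int = 20
    class_weighting: bool = False
    seed: int = 0

    def to_estimator(self) -> "DenseNoiseClassifier":
        return DenseNoiseClassifier(
            hidden_sizes=tuple(self.hidden_sizes),
            noise_sd=self.gaussian_noise_sd,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.early_stop_patience,
            class_weight="balanced" if self.class_weighting else None,
            random_state=self.seed)


class DenseNoiseClassifier(BaseEstimator, ClassifierMixin):
    """3-block dense network with Gaussian-noise regularization.

    Parameters
    ----------
    hidden_sizes : tuple of 3 ints
        Widths of the three hidden blocks (the depth is fixed).
    noise_sd : float
        Standard deviation of the additive Gaussian noise applied to the
        dense-layer outputs during training only.
    class_weight : None or "balanced"
        With "balanced", samples are weighted inversely to class
        frequency in the cross-entropy.
    val_fraction : float
        Fraction of the training data held out (stratified) to monitor
        early stopping; falls back to the training loss when the split
        is too small to stratify.
    """

    def __init__(self, hidden_sizes=(128, 128, 128), noise_sd=0.05,
                 learning_rate=1e-3, batch_size=64, max_epochs=200,
                 patience=20, val_fraction=0.1, class_weight=None,
                 weight_decay=1e-3, random_state=None):
        self.hidden_sizes = hidden_sizes
        self.noise_sd = noise_sd
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.class_weight = class_weight
        self.weight_decay = weight_decay
        self.random_state = random_state

    # -- parameter plumbing -------------------------------------------------

    def _init_params(self, input_dim: int, rng: np.random.Generator) -> dict:
        sizes = [input_dim, *self.hidden_sizes]
        params: dict[str, np.ndarray] = {}
        for l in range(3):
            fan_in = sizes[l]
            params[f"W{l}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                         (sizes[l], sizes[l + 1]))
            params[f"b{l}"] = np.zeros(sizes[l + 1])
            params[f"gamma{l}"] = np.ones(sizes[l + 1])
            params[f"beta{l}"] = np.zeros(sizes[l + 1])
        params["Wo"] = rng.normal(0.0, np.sqrt(1.0 / sizes[-1]), (sizes[-1], 1))
        params["bo"] = np.zeros(1)
        return params

    @property
    def n_parameters_(self) -> int:
        check_is_fitted(self, "params_")
        return int(sum(p.size for p in self.params_.values()))

    # -- forward passes -----------------------------------------------------

    def _forward_train(self, X, rng):
        """Training-mode forward: noise on, batch statistics for BN.
        Returns output probabilities plus a cache for backprop."""
        cache = {"a": [X]}
        a = X
        for l in range(3):
            z = a @ self.params_[f"W{l}"] + self.params_[f"b{l}"]
            if self.noise_sd > 0:
                z = z + rng.normal(0.0, self.noise_sd, z.shape)
            h = np.maximum(z, 0.0)
            mu = h.mean(axis=0)
            var = h.var(axis=0)
            std = np.sqrt(var + _EPS_BN)
            xhat = (h - mu) / std
            y = self.params_[f"gamma{l}"] * xhat + self.params_[f"beta{l}"]
            m = self._momentum
            self.bn_stats_[f"mean{l}"] = m * self.bn_stats_[f"mean{l}"] \
                + (1 - m) * mu
            self.bn_stats_[f"var{l}"] = m * self.bn_stats_[f"var{l}"] \
                + (1 - m) * var
            cache[f"z{l}"], cache[f"xhat{l}"], cache[f"std{l}"] = z, xhat, std
            cache["a"].append(y)
            a = y
        o = a @ self.params_["Wo"] + self.params_["bo"]
        p = _sigmoid(o[:, 0])
        return p, cache

    def _forward_eval(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode forward: noise off, running BN statistics."""
        a = X
        for l in range(3):
            z = a @ self.params_[f"W{l}"] + self.params_[f"b{l}"]
            h = np.maximum(z, 0.0)
            std = np.sqrt(self.bn_stats_[f"var{l}"] + _EPS_BN)
            a = self.params_[f"gamma{l}"] * (h - self.bn_stats_[f"mean{l}"]) \
                / std + self.params_[f"beta{l}"]
        o = a @ self.params_["Wo"] + self.params_["bo"]
        return _sigmoid(o[:, 0])

    def _backward(self, p, yb, wb, cache):
        """Gradient of the weighted BCE w.r.t. every parameter."""
        n = len(yb)
        grads: dict[str, np.ndarray] = {}
        # d(BCE)/d(logit) = (p - y), per-sample weighted
        do = ((p - yb) * wb / wb.sum())[:, None]
        a3 = cache["a"][3]
        grads["Wo"] = a3.T @ do
        grads["bo"] = do.sum(axis=0)
        dy = do @ self.params_["Wo"].T
        for l in range(2, -1, -1):
            xhat, std = cache[f"xhat{l}"], cache[f"std{l}"]
            grads[f"gamma{l}"] = (dy * xhat).sum(axis=0)
            grads[f"beta{l}"] = dy.sum(axis=0)
            dxhat = dy * self.params_[f"gamma{l}"]
            m = xhat.shape[0]
            dh = (dxhat - dxhat.mean(axis=0)
                  - xhat * (dxhat * xhat).mean(axis=0)) / std
            dz = dh * (cache[f"z{l}"] > 0)
            a_prev = cache["a"][l]
            grads[f"W{l}"] = a_prev.T @ dz
            grads[f"b{l}"] = dz.sum(axis=0)
            dy = dz @ self.params_[f"W{l}"].T
        return grads

    @staticmethod
    def _bce(p, y, w):
        p = np.clip(p, _EPS_CLIP, 1.0 - _EPS_CLIP)
        return float(-(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum()
                     / w.sum())

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        if len(tuple(self.hidden_sizes)) != 3 or \
                any(int(h) < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be 3 positive integers")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                "both classes must be present in the training labels")
        y01 = (y == self.classes_[1]).astype(float)
        self.n_features_in_ = X.shape[1]

        rng = np.random.default_rng(self.random_state)
        self.params_ = self._init_params(self.n_features_in_, rng)
        widths = [int(h) for h in self.hidden_sizes]
        self.bn_stats_ = {}
        for l in range(3):
            self.bn_stats_[f"mean{l}"] = np.zeros(widths[l])
            self.bn_stats_[f"var{l}"] = np.ones(widths[l])
        self._momentum = 0.9

        if self.class_weight == "balanced":
            n_pos = y01.sum()
            w = np.where(y01 == 1, len(y01) / (2.0 * n_pos),
                         len(y01) / (2.0 * (len(y01) - n_pos)))
        else:
            w = np.ones_like(y01)

        # stratified early-stopping slice
        n = len(y01)
        use_val = (self.val_fraction > 0
                   and int(n * self.val_fraction) >= 2
                   and min(y01.sum(), n - y01.sum()) >= 2)
        if use_val:
            try:
                idx_tr, idx_va = train_test_split(
                    np.arange(n), test_size=self.val_fraction, stratify=y01,
                    random_state=int(rng.integers(2**31 - 1)))
            except ValueError:
                use_val = False
        if not use_val:
            idx_tr, idx_va = np.arange(n), np.arange(0)
        Xtr, ytr, wtr = X[idx_tr], y01[idx_tr], w[idx_tr]
        Xva, yva, wva = X[idx_va], y01[idx_va], w[idx_va]

        # Adam state
        mstate = {k: np.zeros_like(v) for k, v in self.params_.items()}
        vstate = {k: np.zeros_like(v) for k, v in self.params_.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0

        best_loss, best_params, best_bn, patience_left = np.inf, None, None, \
            self.patience
        history = {"train_loss": [], "val_loss": []}
        bs = max(int(self.batch_size), 2)
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(ytr))
            losses = []
            for start in range(0, len(order), bs):
                batch = order[start:start + bs]
                if len(batch) < 2:   # batch-norm needs >= 2 samples
                    continue
                p, cache = self._forward_train(Xtr[batch], rng)
                losses.append(self._bce(p, ytr[batch], wtr[batch]))
                grads = self._backward(p, ytr[batch], wtr[batch], cache)
                step += 1
                lr_t = self.learning_rate * \
                    np.sqrt(1 - b2**step) / (1 - b1**step)
                for k, g in grads.items():
                    mstate[k] = b1 * mstate[k] + (1 - b1) * g
                    vstate[k] = b2 * vstate[k] + (1 - b2) * g * g
                    self.params_[k] -= lr_t * mstate[k] / \
                        (np.sqrt(vstate[k]) + eps)
                    if self.weight_decay > 0 and k.startswith("W"):
                        # decoupled weight decay on dense weights only
                        self.params_[k] *= 1.0 - \
                            self.learning_rate * self.weight_decay
            history["train_loss"].append(float(np.mean(losses)))
            if len(idx_va):
                monitor = self._bce(self._forward_eval(Xva), yva, wva)
            else:
                monitor = history["train_loss"][-1]
            history["val_loss"].append(monitor)
            if monitor < best_loss - 1e-6:
                best_loss = monitor
                best_params = {k: v.copy() for k, v in self.params_.items()}
                best_bn = {k: v.copy() for k, v in self.bn_stats_.items()}
                patience_left = self.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_params is not None:
            self.params_, self.bn_stats_ = best_params, best_bn
        self.history_ = history
        self.n_epochs_ = len(history["train_loss"])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects "
                f"{self.n_features_in_}")
        p = self._forward_eval(X)
        return np.column_stack([1.0 - p, p])

    def predict_score(self, X) -> np.ndarray:
        """The DNN score ŷ ∈ (0, 1) for each row."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_score(X) >= 0.5).astype(int)]

    def input_gradient(self, X) -> np.ndarray:
        """Exact ∂ŷ/∂x in inference mode (noise off, frozen batch norm),
        one gradient row per input row — the basis of saliency maps."""
        check_is_fitted(self, "params_")
        X = check_array(X)
        acts, masks, scales = [X], [], []
        a = X
        for l in range(3):
            z = a @ self.params_[f"W{l}"] + self.params_[f"b{l}"]
            masks.append(z > 0)
            h = np.maximum(z, 0.0)
            std = np.sqrt(self.bn_stats_[f"var{l}"] + _EPS_BN)
            scales.append(self.params_[f"gamma{l}"] / std)
            a = scales[-1] * (h - self.bn_stats_[f"mean{l}"]) \
                + self.params_[f"beta{l}"]
            acts.append(a)
        o = a @ self.params_["Wo"] + self.params_["bo"]
        p = _sigmoid(o[:, 0])
        delta = (p * (1 - p))[:, None] * self.params_["Wo"].T  # (n, h3)
        for l in range(2, -1, -1):
            delta = delta * scales[l] * masks[l]
            delta = delta @ self.params_[f"W{l}"].T
        return delta


class FoldEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of one dense classifier per stratified k-fold complement.

    Member *j* trains on every fold except *j*; a patient's score is the
    arithmetic mean of the member sigmoids, with the member spread
    reported alongside.  Defaults to the 7-fold scheme.
    """

    def __init__(self, estimator: DenseNoiseClassifier | None = None,
                 n_folds: int = 7, random_state=None):
        self.estimator = estimator
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("both classes must be present")
        if len(y) < self.n_folds:
            raise ValueError("need at least n_folds samples")
        base = self.estimator if self.estimator is not None \
            else DenseNoiseClassifier()
        ss = np.random.SeedSequence(self.random_state)

        folds = None
        for attempt in range(5):
            seed = int(np.random.default_rng(ss.spawn(1)[0]
                                             ).integers(2**31 - 1)) + attempt
            skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                                  random_state=seed % (2**31 - 1))
            trial = list(skf.split(X, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in trial):
                folds = trial
                break
        if folds is None:
            raise ValueError(
                "could not stratify folds with both classes in every "
                "training split after 5 attempts")

        member_seeds = ss.spawn(self.n_folds)
        self.members_, self.fold_indices_, self.train_indices_ = [], [], []
        for j, (tr, va) in enumerate(folds):
            member = clone(base)
            member.set_params(random_state=int(
                np.random.default_rng(member_seeds[j]).integers(2**31 - 1)))
            member.fit(X[tr], y[tr])
            self.members_.append(member)
            self.fold_indices_.append(va)
            self.train_indices_.append(tr)
        self.n_features_in_ = X.shape[1]
        # held-out score per training patient: each row scored by the one
        # member whose validation fold contains it
        self.oof_scores_ = np.empty(len(y))
        for member, va in zip(self.members_, self.fold_indices_):
            self.oof_scores_[va] = member.predict_score(X[va])
        return self

    def member_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        return np.column_stack([m.predict_score(X) for m in self.members_])

    def predict_score(self, X, return_sd: bool = False):
        scores = self.member_scores(X)
        mean = scores.mean(axis=1)
        if return_sd:
            return mean, scores.std(axis=1, ddof=1)
        return mean

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_score(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_score(X) >= 0.5).astype(int)]

    def input_gradient(self, X) -> np.ndarray:
        """Mean input gradient across the ensemble members."""
        grads = [m.input_gradient(X) for m in self.members_]
        return np.mean(grads, axis=0)


def small_cohort_estimator(width: int = 16,
                           max_epochs: int = 60) -> DenseNoiseClassifier:
    """Classifier configuration recommended for leave-one-out studies on
    very small cohorts (n ≲ 60).

    Early stopping is disabled — a validation slice of a few patients is
    too noisy to monitor — and inverse-frequency class weighting is on so
    that the score's operating point does not drift with the training
    prevalence, which leave-one-out perturbs systematically (withholding
    a positive lowers the training prevalence and would otherwise bias
    every held-out positive's score downward).
    """
    return DenseNoiseClassifier(
        hidden_sizes=(width, width, width), max_epochs=max_epochs,
        patience=max_epochs, val_fraction=0.0, class_weight="balanced")


# ---------------------------------------------------------------------------
# thin functional wrappers

def build_model(config: ModelConfig, input_dim: int) -> DenseNoiseClassifier:
    """Instantiate an untrained classifier with seeded initial parameters
    materialized for *input_dim* inputs."""
    est = config.to_estimator()
    rng = np.random.default_rng(config.seed)
    est.params_ = est._init_params(input_dim, rng)
    est.bn_stats_ = {}
    for l in range(3):
        w = int(config.hidden_sizes[l])
        est.bn_stats_[f"mean{l}"] = np.zeros(w)
        est.bn_stats_[f"var{l}"] = np.ones(w)
    est.n_features_in_ = input_dim
    est.classes_ = np.array([0, 1])
    return est


def train_model(model: DenseNoiseClassifier, X, y,
                config: ModelConfig | None = None) -> DenseNoiseClassifier:
    if config is not None:
        model.set_params(**config.to_estimator().get_params())
    return model.fit(X, y)


def predict_score(model, x) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return model.predict_score(x)


def ensemble_score(ensemble: FoldEnsembleClassifier, x
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard deviation of the member scores for *x*."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return ensemble.predict_score(x, return_sd=True)


# ---------------------------------------------------------------------------
# serialization: one npz archive per model / ensemble

def save_model(model, path: str | Path) -> Path:
    import json

    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    if isinstance(model, FoldEnsembleClassifier):
        meta = {"kind": "ensemble", "n_folds": model.n_folds,
                "params": {k: v for k, v in model.get_params(deep=False).items()
                           if k != "estimator"}}
        for j, m in enumerate(model.members_):
            for k, v in m.params_.items():
                arrays[f"m{j}_{k}"] = v
            for k, v in m.bn_stats_.items():
                arrays[f"m{j}_bn_{k}"] = v
        meta["member_params"] = [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in m.get_params().items()} for m in model.members_]
        meta["n_features_in"] = int(model.n_features_in_)
    else:
        meta = {"kind": "single",
                "params": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in model.get_params().items()},
                "n_features_in": int(model.n_features_in_)}
        for k, v in model.params_.items():
            arrays[k] = v
        for k, v in model.bn_stats_.items():
            arrays[f"bn_{k}"] = v
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def _restore_single(param_kwargs: dict, arrays: dict, prefix: str = ""
                    ) -> DenseNoiseClassifier:
    if "hidden_sizes" in param_kwargs:
        param_kwargs["hidden_sizes"] = tuple(param_kwargs["hidden_sizes"])
    est = DenseNoiseClassifier(**param_kwargs)
    est.params_ = {k[len(prefix):]: arrays[k] for k in arrays
                   if k.startswith(prefix) and "_bn_" not in k
                   and not (prefix == "" and k.startswith("bn_"))}
    bn_prefix = f"{prefix}bn_" if prefix else "bn_"
    est.bn_stats_ = {k[len(bn_prefix):]: arrays[k] for k in arrays
                     if k.startswith(bn_prefix)}
    est.classes_ = np.array([0, 1])
    return est


def load_model(path: str | Path):
    import json

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    if meta["kind"] == "single":
        est = _restore_single(meta["params"], arrays)
        est.n_features_in_ = meta["n_features_in"]
        return est
    ens = FoldEnsembleClassifier(**meta["params"])
    ens.members_ = []
    for j, pkw in enumerate(meta["member_params"]):
        sub = {k: v for k, v in arrays.items() if k.startswith(f"m{j}_")}
        member = _restore_single(pkw, sub, prefix=f"m{j}_")
        member.n_features_in_ = meta["n_features_in"]
        ens.members_.append(member)
    ens.classes_ = np.array([0, 1])
    ens.n_features_in_ = meta["n_features_in"]
    ens.fold_indices_ = []
    return ens
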