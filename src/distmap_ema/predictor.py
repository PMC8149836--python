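"""K-fold ensemble and two-stage stacked feed-forward quality regressors.

The regressor is a five-dense-layer network (256/128/64/32/1 units by
default) with rectifier hidden activations and a logistic output so
predictions live in [0, 1]. A batch-normalization layer sits between the
second and third dense layers and dropout (rate 0.2) follows the first and
third. Training minimises mean-squared error with Adam and early stopping
on held-out-fold MSE.

Training data are split into K folds *by target*, so no target's decoys
leak between a member's training and validation sets. Stage-1 trains K
members (member k validates on fold k); predictions either average the K
outputs or feed a stage-2 stacker whose input is the original features
concatenated with the K stage-1 outputs.

The network is implemented directly on numpy: the architecture (batch-norm
placement, dropout positions, logistic head) is part of the method, and a
few hundred training rows need no GPU framework.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import DataError

logger = logging.getLogger(__name__)

KEY_COLUMNS = ("target_id", "model_id")


@dataclass
class NetworkConfig:
    """Architecture and optimisation settings of one quality regressor."""

    widths: tuple[int, ...] = (256, 128, 64, 32, 1)
    batchnorm_after: int = 2       # between 2nd and 3rd dense layer
    dropout_after: tuple[int, ...] = (1, 3)
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 150
    batch_size: int = 64
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.widths) < 2 or self.widths[-1] != 1:
            raise ValueError("need >= 2 layers with output width 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class DenseNet:
    """Small fully connected regressor with batch norm and dropout."""

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.9

    def __init__(self, n_inputs: int, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dims = [n_inputs, *config.widths]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(d) for d in dims[1:]]
        bn_dim = config.widths[config.batchnorm_after - 1]
        self.gamma = np.ones(bn_dim)
        self.beta = np.zeros(bn_dim)
        self.run_mean = np.zeros(bn_dim)
        self.run_var = np.ones(bn_dim)
        self._rng = rng

    # -- forward -----------------------------------------------------------

    def _forward(self, X, training: bool):
        cfg = self.config
        cache = {"h": [X], "drop": {}, "bn": None}
        h = X
        n_layers = len(self.W)
        for layer in range(1, n_layers + 1):
            z = h @ self.W[layer - 1] + self.b[layer - 1]
            if layer == n_layers:
                h = _sigmoid(z)
                cache.setdefault("z", []).append(z)
                cache["h"].append(h)
                break
            h = _relu(z)
            cache.setdefault("z", []).append(z)
            if layer == cfg.batchnorm_after:
                if training:
                    mu = h.mean(axis=0)
                    var = h.var(axis=0)
                    self.run_mean = self.BN_MOMENTUM * self.run_mean + (1 - self.BN_MOMENTUM) * mu
                    self.run_var = self.BN_MOMENTUM * self.run_var + (1 - self.BN_MOMENTUM) * var
                else:
                    mu, var = self.run_mean, self.run_var
                xhat = (h - mu) / np.sqrt(var + self.BN_EPS)
                cache["bn"] = {"x": h, "xhat": xhat, "mu": mu, "var": var}
                h = self.gamma * xhat + self.beta
            if training and layer in cfg.dropout_after and cfg.dropout_rate > 0:
                keep = 1.0 - cfg.dropout_rate
                mask = (self._rng.random(h.shape) < keep) / keep
                cache["drop"][layer] = mask
                h = h * mask
            cache["h"].append(h)
        return h, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return out[:, 0]

    # -- backward ----------------------------------------------------------

    def _backward(self, cache, y):
        cfg = self.config
        n_layers = len(self.W)
        grads_W = [None] * n_layers
        grads_b = [None] * n_layers
        g_gamma = np.zeros_like(self.gamma)
        g_beta = np.zeros_like(self.beta)
        out = cache["h"][-1]
        n = len(y)
        # d MSE / d out, then through the logistic head
        delta = (2.0 / n) * (out[:, 0] - y)[:, None] * out * (1.0 - out)
        for layer in range(n_layers, 0, -1):
            h_in = cache["h"][layer - 1]
            grads_W[layer - 1] = h_in.T @ delta
            grads_b[layer - 1] = delta.sum(axis=0)
            if layer == 1:
                break
            delta = delta @ self.W[layer - 1].T  # grad wrt h_{layer-1} (post-processing)
            prev = layer - 1
            if prev in cache["drop"]:
                delta = delta * cache["drop"][prev]
            if prev == cfg.batchnorm_after and cache["bn"] is not None:
                bn = cache["bn"]
                xhat, var = bn["xhat"], bn["var"]
                m = len(xhat)
                g_gamma = (delta * xhat).sum(axis=0)
                g_beta = delta.sum(axis=0)
                dxhat = delta * self.gamma
                inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
                delta = (inv_std / m) * (
                    m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
                )
            delta = delta * (cache["z"][prev - 1] > 0)
        return grads_W, grads_b, g_gamma, g_beta

    # -- training ----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None) -> dict:
        """Train with Adam + early stopping; returns a small history dict."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        params = self.W + self.b + [self.gamma, self.beta]
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_state = None
        bad_epochs = 0
        history = {"val_mse": []}
        n = len(X)
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                if len(idx) < 2:
                    continue  # batch statistics need >= 2 rows
                _, cache = self._forward(X[idx], training=True)
                gW, gb, ggamma, gbeta = self._backward(cache, y[idx])
                grads = gW + gb + [ggamma, gbeta]
                step += 1
                params = self.W + self.b + [self.gamma, self.beta]
                for p, g, mt, vt in zip(params, grads, m_t, v_t):
                    mt *= beta1
                    mt += (1 - beta1) * g
                    vt *= beta2
                    vt += (1 - beta2) * g * g
                    mhat = mt / (1 - beta1 ** step)
                    vhat = vt / (1 - beta2 ** step)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if X_val is not None and len(X_val):
                val_mse = float(np.mean((self.predict(X_val) - y_val) ** 2))
                history["val_mse"].append(val_mse)
                if val_mse < best_val - 1e-9:
                    best_val = val_mse
                    best_state = self.get_state()
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs > cfg.patience:
                        break
        if best_state is not None:
            self.set_state(best_state)
            history["best_val_mse"] = best_val
        return history

    # -- (de)serialisation -------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            state[f"W{i}"] = W.copy()
            state[f"b{i}"] = b.copy()
        state["gamma"] = self.gamma.copy()
        state["beta"] = self.beta.copy()
        state["run_mean"] = self.run_mean.copy()
        state["run_var"] = self.run_var.copy()
        return state

    def set_state(self, state) -> None:
        for i in range(len(self.W)):
            self.W[i] = np.array(state[f"W{i}"])
            self.b[i] = np.array(state[f"b{i}"])
        self.gamma = np.array(state["gamma"])
        self.beta = np.array(state["beta"])
        self.run_mean = np.array(state["run_mean"])
        self.run_var = np.array(state["run_var"])


# ---------------------------------------------------------------------------
# dataset plumbing


def split_features_labels(features: pd.DataFrame, labels: pd.DataFrame):
    """Join a feature table and a label table on (target_id, model_id)."""
    for col in KEY_COLUMNS:
        if col not in features.columns or col not in labels.columns:
            raise DataError(f"both tables need a {col!r} column")
    if "label" not in labels.columns:
        raise DataError("label table needs a 'label' column")
    merged = features.merge(labels[[*KEY_COLUMNS, "label"]], on=list(KEY_COLUMNS))
    if len(merged) != len(features):
        raise DataError("feature and label tables do not align on keys")
    if ((merged["label"] < 0) | (merged["label"] > 1)).any():
        raise DataError("labels must lie in [0, 1]")
    return merged


def make_folds(targets, K: int, seed: int) -> dict[str, int]:
    """Deterministic partition of targets into K folds of near-equal size."""
    targets = list(targets)
    if K < 2:
        raise DataError("K must be >= 2")
    if K > len(targets):
        raise DataError(f"K={K} exceeds the number of targets ({len(targets)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(targets))
    return {str(t): i % K for i, t in enumerate(order)}


@dataclass
class Ensemble:
    """A trained stage-1 fold ensemble with optional stage-2 stacker."""

    preset: str
    feature_columns: list[str]
    config: NetworkConfig
    K: int
    folds: dict[str, int]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    members: list[DenseNet] = field(default_factory=list)
    stage2: DenseNet | None = None
    stage2_mean: np.ndarray | None = None
    stage2_std: np.ndarray | None = None

    # -- feature handling --------------------------------------------------

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in features.columns]
        if missing:
            raise DataError(f"missing feature columns: {', '.join(missing)}")
        X = features[self.feature_columns].to_numpy(dtype=float)
        Xs = (X - self.scaler_mean) / self.scaler_std
        if not np.isfinite(Xs).all():
            bad = np.asarray(self.feature_columns)[~np.isfinite(Xs).all(axis=0)]
            raise DataError(
                f"non-finite values after standardization in columns: {', '.join(bad)}"
            )
        return Xs

    def member_outputs(self, features: pd.DataFrame) -> np.ndarray:
        Xs = self._matrix(features)
        return np.column_stack([m.predict(Xs) for m in self.members])

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Ensemble prediction in [0, 1]: stage-2 output if stacked, else mean."""
        outs = self.member_outputs(features)
        if self.stage2 is None:
            return np.clip(outs.mean(axis=1), 0.0, 1.0)
        Xs = self._matrix(features)
        Z = np.column_stack([features[self.feature_columns].to_numpy(dtype=float), outs])
        Z = (Z - self.stage2_mean) / self.stage2_std
        return np.clip(self.stage2.predict(Z), 0.0, 1.0)

    # -- persistence -------------------------------------------------------

    def save(self, model_dir) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "preset": self.preset,
            "feature_columns": self.feature_columns,
            "K": self.K,
            "folds": self.folds,
            "config": {**asdict(self.config),
                       "widths": list(self.config.widths),
                       "dropout_after": list(self.config.dropout_after)},
            "two_stage": self.stage2 is not None,
        }
        (model_dir / "config.json").write_text(json.dumps(meta, indent=2))
        arrays = {"scaler_mean": self.scaler_mean, "scaler_std": self.scaler_std}
        if self.stage2_mean is not None:
            arrays["stage2_mean"] = self.stage2_mean
            arrays["stage2_std"] = self.stage2_std
        np.savez(model_dir / "scaler.npz", **arrays)
        for k, member in enumerate(self.members):
            np.savez(model_dir / f"member_{k}.npz", **member.get_state())
        if self.stage2 is not None:
            np.savez(model_dir / "stage2.npz", **self.stage2.get_state())

    @classmethod
    def load(cls, model_dir) -> "Ensemble":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "config.json").read_text())
        cfg_dict = dict(meta["config"])
        cfg_dict["widths"] = tuple(cfg_dict["widths"])
        cfg_dict["dropout_after"] = tuple(cfg_dict["dropout_after"])
        config = NetworkConfig(**cfg_dict)
        scaler = np.load(model_dir / "scaler.npz")
        n_features = len(meta["feature_columns"])
        ens = cls(
            preset=meta["preset"],
            feature_columns=list(meta["feature_columns"]),
            config=config,
            K=meta["K"],
            folds={str(k): int(v) for k, v in meta["folds"].items()},
            scaler_mean=scaler["scaler_mean"],
            scaler_std=scaler["scaler_std"],
        )
        for k in range(meta["K"]):
            net = DenseNet(n_features, config)
            net.set_state(np.load(model_dir / f"member_{k}.npz"))
            ens.members.append(net)
        if meta["two_stage"]:
            ens.stage2 = DenseNet(n_features + meta["K"], config)
            ens.stage2.set_state(np.load(model_dir / "stage2.npz"))
            ens.stage2_mean = scaler["stage2_mean"]
            ens.stage2_std = scaler["stage2_std"]
        return ens


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    constant = std < 1e-12
    if constant.any():
        logger.info("constant feature columns standardized to 0 (std set to 1)")
        std = np.where(constant, 1.0, std)
    return mean, std


def train_kfold(features: pd.DataFrame, labels: pd.DataFrame, K: int,
                config: NetworkConfig, preset: str = "deep",
                feature_columns: list[str] | None = None) -> Ensemble:
    """Train the stage-1 K-fold ensemble (member k validates on fold k)."""
    data = split_features_labels(features, labels)
    if feature_columns is None:
        feature_columns = [c for c in features.columns if c not in KEY_COLUMNS]
    folds = make_folds(data["target_id"].unique(), K, config.seed)
    fold_of_row = data["target_id"].map(folds).to_numpy()

    X = data[feature_columns].to_numpy(dtype=float)
    y = data["label"].to_numpy(dtype=float)
    mean, std = _standardize_fit(X)
    Xs = (X - mean) / std
    if not np.isfinite(Xs).all():
        bad = np.asarray(feature_columns)[~np.isfinite(Xs).all(axis=0)]
        raise DataError(
            f"non-finite values after standardization in columns: {', '.join(bad)}"
        )

    ens = Ensemble(
        preset=preset, feature_columns=list(feature_columns), config=config,
        K=K, folds=folds, scaler_mean=mean, scaler_std=std,
    )
    for k in range(K):
        member_cfg = NetworkConfig(**{**asdict(config), "seed": config.seed + 1000 + k})
        net = DenseNet(len(feature_columns), member_cfg)
        train_idx = fold_of_row != k
        val_idx = ~train_idx
        hist = net.fit(Xs[train_idx], y[train_idx], Xs[val_idx], y[val_idx])
        logger.info("stage-1 member %d: best validation MSE %.5f", k,
                    hist.get("best_val_mse", float("nan")))
        ens.members.append(net)
    return ens


def train_two_stage(features: pd.DataFrame, labels: pd.DataFrame, K: int,
                    config: NetworkConfig, preset: str = "deep",
                    feature_columns: list[str] | None = None) -> Ensemble:
    """Stage-1 ensemble plus a stage-2 stacker on [features ∥ K outputs].

    The stacker is trained on the same structural models as stage 1, using
    the same fold partition; fold 0 serves as its early-stopping validation
    split.
    """
    ens = train_kfold(features, labels, K, config, preset, feature_columns)
    data = split_features_labels(features, labels)
    outs = ens.member_outputs(data)
    Z = np.column_stack([data[ens.feature_columns].to_numpy(dtype=float), outs])
    mean, std = _standardize_fit(Z)
    Zs = (Z - mean) / std
    y = data["label"].to_numpy(dtype=float)
    fold_of_row = data["target_id"].map(ens.folds).to_numpy()
    val_idx = fold_of_row == 0
    stage2_cfg = NetworkConfig(**{**asdict(config), "seed": config.seed + 2000})
    stage2 = DenseNet(Zs.shape[1], stage2_cfg)
    hist = stage2.fit(Zs[~val_idx], y[~val_idx], Zs[val_idx], y[val_idx])
    logger.info("stage-2 stacker: best validation MSE %.5f",
                hist.get("best_val_mse", float("nan")))
    ens.stage2 = stage2
    ens.stage2_mean = mean
    ens.stage2_std = std
    return ens


def predict_average(ensemble: Ensemble, features: pd.DataFrame) -> np.ndarray:
    """Arithmetic mean of stage-1 member outputs, clamped to [0, 1]."""
    return np.clip(ensemble.member_outputs(features).mean(axis=1), 0.0, 1.0)


# ---------------------------------------------------------------------------
# end-to-end target prediction


def predict_target(ensemble: Ensemble, target, models, pdm, contacts=None,
                   externals: pd.DataFrame | None = None,
                   consensus: np.ndarray | None = None) -> pd.DataFrame:
    """Featurize and score a pool of models for one target.

    Raw network outputs are normalised by each model's present-residue
    fraction (partial-model rule). If the target declares domains, each
    domain slice is featurized and scored separately and the domain scores
    are averaged.
    """
    from .map_features import (
        CONSENSUS_FEATURE,
        DIST_FEATURES,
        PRESETS,
        compute_artifacts,
        featurize_model,
    )
    from .scoring import domain_average, normalize_partial, pairwise_consensus
    from .structio import DistanceMap, TargetRecord

    preset = ensemble.preset
    ext_by_model: dict[str, dict[str, float]] = {}
    if externals is not None:
        ext_cols = [c for c in externals.columns if c not in KEY_COLUMNS]
        for _, row in externals.iterrows():
            ext_by_model[str(row["model_id"])] = {c: float(row[c]) for c in ext_cols}

    needs_consensus = CONSENSUS_FEATURE in PRESETS[preset]["internal"]
    if needs_consensus and consensus is None:
        consensus = pairwise_consensus(list(models))

    needs_maps = bool(set(PRESETS[preset]["internal"])
                      & (set(DIST_FEATURES) | {"correlation_feature"}))
    spans = list(target.domains) if target.domains else [(1, target.L)]
    span_inputs = []
    for (start, end) in spans:
        if len(spans) == 1:
            sub_target, sub_pdm, sub_contacts = target, pdm, contacts
        else:
            sub_target = TargetRecord(
                target_id=target.target_id,
                sequence=target.sequence[start - 1:end],
            )
            sub_pdm = DistanceMap(
                values=pdm.values[start - 1:end, start - 1:end],
                observed=pdm.observed[start - 1:end, start - 1:end],
            )
            sub_contacts = contacts.slice_domain(start, end) if contacts else None
        pdm_art = compute_artifacts(sub_pdm) if needs_maps else None
        span_inputs.append((sub_target, sub_pdm, sub_contacts, pdm_art))

    rows = []
    for m_idx, model in enumerate(models):
        domain_scores = []
        for (start, end), (sub_target, sub_pdm, sub_contacts, pdm_art) in zip(
                spans, span_inputs):
            sub_model = model if len(spans) == 1 else model.slice_domain(start, end)
            if sub_model.n_present < 2:
                domain_scores.append(0.0)
                continue
            fv = featurize_model(
                sub_target, sub_model, sub_pdm, contacts=sub_contacts,
                externals=ext_by_model.get(model.model_id),
                preset=preset,
                consensus=None if consensus is None else float(consensus[m_idx]),
                allow_missing_externals=True,
                pdm_artifacts=pdm_art,
            )
            frame = pd.DataFrame([{**dict(zip(KEY_COLUMNS, (target.target_id, model.model_id))),
                                   **fv.values}])
            raw = float(ensemble.predict(frame)[0])
            domain_scores.append(
                normalize_partial(raw, sub_model.n_present, sub_target.L)
            )
        rows.append({
            "target_id": target.target_id,
            "model_id": model.model_id,
            "score": domain_average(domain_scores),
        })
    return pd.DataFrame(rows)
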