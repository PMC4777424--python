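"""From-scratch shallow neural network predicting 3-month hemoglobin change.

The regressor is a fixed feed-forward architecture
``n_features -> 10 -> 10 -> 1`` with tanh hidden units and a linear output,
trained by minimizing mean squared error of the predicted vs observed
``delta_hb = Hb(t+3 months) - Hb(t)``.  The forward pass, loss and backprop
gradient are implemented here explicitly (the gradient is verified against
central finite differences in the test suite); the default driver is L-BFGS
(scipy's generic quasi-Newton minimizer fed with our gradient), with
full-batch gradient descent plus momentum as the configurable alternative.
Early stopping monitors an inner validation slice of the training split.

Records are split 60/40 at the record level by default (each Hb-anchored
record is an independent example); a patient-level split, which never places
records of one patient on both sides, is available as the methodologically
safer option.  Feature imputation (training-split medians) and
standardization are fitted on the training split only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "SplitSpec",
    "Hyperparams",
    "FeaturePipeline",
    "TrainedModel",
    "split_records",
    "train",
    "predict",
    "init_params",
    "forward",
    "loss_and_grad",
    "NUMERIC_FEATURES",
    "CATEGORICAL_FEATURES",
]

NUMERIC_FEATURES = [
    "age", "height", "vintage", "hb_t",
    "duration", "sessions_per_week", "ektv_mean", "ektv_sd",
    "pre_weight", "post_weight",
    "esa_dose_90d", "iron_dose_90d",
    "ferritin", "tsat", "albumin", "phosphate", "crp",
    "esa_future", "iron_future",
]
#: categorical raw columns with their fixed one-hot vocabularies
CATEGORICAL_FEATURES = {
    "modality": ("LFHD", "HFHD", "HDF"),
    "vascular_access": ("fistula", "graft", "catheter"),
}
BINARY_FEATURES = {"sex": "male", "diabetes": 1}   # encoded as indicator of the value


@dataclass
class SplitSpec:
    """Train/test partition: fraction, level ('record' or 'patient'), seed."""

    train_frac: float = 0.60
    level: str = "record"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if self.level not in ("record", "patient"):
            raise ValueError(f"unknown split level {self.level!r}")


@dataclass
class Hyperparams:
    hidden: tuple = (10, 10)
    solver: str = "lbfgs"            # 'lbfgs' | 'gd'
    max_epochs: int = 2000
    patience: int = 50
    val_fraction: float = 0.15
    learning_rate: float = 0.05      # gd only
    momentum: float = 0.9            # gd only

    def validate(self) -> None:
        if self.solver not in ("lbfgs", "gd"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.max_epochs < 1 or self.patience < 1:
            raise ValueError("max_epochs and patience must be >= 1")


def split_records(records: pd.DataFrame, spec: SplitSpec):
    """Partition valid records into disjoint, exhaustive train/test id lists."""
    spec.validate()
    valid = records[records["valid"].astype(bool)]
    n = len(valid)
    if n < 2:
        raise ValueError(f"need at least 2 valid records to split, got {n}")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    ids = valid["record_id"].to_numpy()

    if spec.level == "record":
        order = rng.permutation(n)
        n_train = int(round(spec.train_frac * n))
        n_train = min(max(n_train, 1), n - 1)
        train_ids = ids[order[:n_train]]
        test_ids = ids[order[n_train:]]
    else:
        patients = valid["patient_id"].to_numpy()
        uniq = np.array(sorted(set(patients)))
        rng.shuffle(uniq)
        counts = valid["patient_id"].value_counts()
        target = spec.train_frac * n
        train_patients, acc = set(), 0
        for pid in uniq:
            if acc >= target and len(train_patients) > 0:
                break
            train_patients.add(pid)
            acc += int(counts[pid])
        if len(train_patients) == len(uniq):        # keep test side non-empty
            train_patients.discard(uniq[-1])
        in_train = np.array([p in train_patients for p in patients])
        train_ids, test_ids = ids[in_train], ids[~in_train]

    return sorted(train_ids.tolist()), sorted(test_ids.tolist())


# ---------------------------------------------------------------------------
# feature pipeline
# ---------------------------------------------------------------------------

@dataclass
class FeaturePipeline:
    """Median imputation + fixed categorical encoding + standardization.

    All statistics (medians, centers, scales) are fitted on the training
    split only and frozen thereafter.
    """

    feature_names: list = field(default_factory=list)
    medians: dict = field(default_factory=dict)
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None

    def _raw_matrix(self, df: pd.DataFrame) -> np.ndarray:
        required = NUMERIC_FEATURES + list(CATEGORICAL_FEATURES) + list(BINARY_FEATURES)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"records are missing feature columns: {missing}")
        cols = []
        names = []
        for col in NUMERIC_FEATURES:
            cols.append(df[col].to_numpy(dtype=float))
            names.append(col)
        for col, positive in BINARY_FEATURES.items():
            cols.append((df[col] == positive).to_numpy(dtype=float))
            names.append(f"{col}_{positive}")
        for col, vocab in CATEGORICAL_FEATURES.items():
            for level in vocab:
                cols.append((df[col] == level).to_numpy(dtype=float))
                names.append(f"{col}_{level}")
        self._names_tmp = names
        return np.column_stack(cols) if len(df) else np.empty((0, len(names)))

    def fit(self, df: pd.DataFrame) -> "FeaturePipeline":
        X = self._raw_matrix(df)
        self.feature_names = list(self._names_tmp)
        self.medians = {}
        for j, name in enumerate(self.feature_names):
            col = X[:, j]
            finite = col[np.isfinite(col)]
            med = float(np.median(finite)) if len(finite) else 0.0
            self.medians[name] = med
            col[~np.isfinite(col)] = med
        self.centers = X.mean(axis=0)
        scales = X.std(axis=0)
        scales[scales == 0] = 1.0
        self.scales = scales
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if self.centers is None:
            raise RuntimeError("pipeline not fitted")
        X = self._raw_matrix(df)
        if self._names_tmp != self.feature_names:
            raise ValueError("feature schema mismatch with the fitted pipeline")
        for j, name in enumerate(self.feature_names):
            col = X[:, j]
            col[~np.isfinite(col)] = self.medians[name]
        return (X - self.centers) / self.scales

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "medians": self.medians,
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeaturePipeline":
        return cls(feature_names=list(d["feature_names"]),
                   medians=dict(d["medians"]),
                   centers=np.asarray(d["centers"], dtype=float),
                   scales=np.asarray(d["scales"], dtype=float))


# ---------------------------------------------------------------------------
# network core
# ---------------------------------------------------------------------------

def init_params(sizes, rng: np.random.Generator):
    """Small uniform weights, U(-1/sqrt(fan_in), +1/sqrt(fan_in)); zero biases."""
    params = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        r = 1.0 / np.sqrt(n_in)
        params.append((rng.uniform(-r, r, size=(n_in, n_out)), np.zeros(n_out)))
    return params


def forward(params, X: np.ndarray) -> list:
    """Activations per layer; tanh hidden units, identity output."""
    acts = [X]
    for li, (W, b) in enumerate(params):
        z = acts[-1] @ W + b
        acts.append(z if li == len(params) - 1 else np.tanh(z))
    return acts


def predict_net(params, X: np.ndarray) -> np.ndarray:
    return forward(params, X)[-1][:, 0]


def loss_and_grad(params, X: np.ndarray, y: np.ndarray):
    """Mean-squared-error loss and its gradient w.r.t. every weight/bias.

    Backpropagation: with L = mean((yhat - y)^2), the output delta is
    2*(yhat - y)/n; hidden deltas are propagated through W and the tanh
    derivative (1 - a^2).
    """
    n = len(y)
    acts = forward(params, X)
    yhat = acts[-1][:, 0]
    resid = yhat - y
    loss = float(np.mean(resid ** 2))

    grads = [None] * len(params)
    delta = (2.0 * resid / n)[:, None]                       # dL/dz at output
    for li in range(len(params) - 1, -1, -1):
        a_prev = acts[li]
        grads[li] = (a_prev.T @ delta, delta.sum(axis=0))
        if li > 0:
            W, _ = params[li]
            delta = (delta @ W.T) * (1.0 - acts[li] ** 2)    # tanh'
    return loss, grads


def _flatten(params) -> np.ndarray:
    return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in params])


def _unflatten(theta: np.ndarray, sizes) -> list:
    params, pos = [], 0
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        W = theta[pos:pos + n_in * n_out].reshape(n_in, n_out)
        pos += n_in * n_out
        b = theta[pos:pos + n_out]
        pos += n_out
        params.append((W, b))
    return params


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Frozen network weights + feature pipeline + split identity."""

    sizes: list
    params: list                     # [(W, b), ...]
    pipeline: FeaturePipeline
    seed: int
    train_ids: list
    test_ids: list
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "schema": "hbforecast-model-v1",
            "sizes": list(self.sizes),
            "weights": [[W.tolist(), b.tolist()] for W, b in self.params],
            "pipeline": self.pipeline.to_dict(),
            "seed": self.seed,
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "metadata": self.metadata,
        })

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        params = [(np.asarray(W, dtype=float), np.asarray(b, dtype=float))
                  for W, b in d["weights"]]
        return cls(sizes=list(d["sizes"]), params=params,
                   pipeline=FeaturePipeline.from_dict(d["pipeline"]),
                   seed=d["seed"], train_ids=d["train_ids"], test_ids=d["test_ids"],
                   metadata=d.get("metadata", {}))

    def save(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "TrainedModel":
        from pathlib import Path
        return cls.from_json(Path(path).read_text())


def _fit_gd(sizes, X, y, X_val, y_val, hyper: Hyperparams, rng):
    theta = _flatten(init_params(sizes, rng))
    velocity = np.zeros_like(theta)
    best_theta, best_val, since_best = theta.copy(), np.inf, 0
    epochs = 0
    for epoch in range(hyper.max_epochs):
        params = _unflatten(theta, sizes)
        loss, grads = loss_and_grad(params, X, y)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        g = _flatten(grads)
        velocity = hyper.momentum * velocity - hyper.learning_rate * g
        theta = theta + velocity
        epochs = epoch + 1
        if X_val is not None:
            val = float(np.mean((predict_net(_unflatten(theta, sizes), X_val) - y_val) ** 2))
            if val < best_val - 1e-12:
                best_val, best_theta, since_best = val, theta.copy(), 0
            else:
                since_best += 1
                if since_best >= hyper.patience:
                    break
    final = best_theta if X_val is not None else theta
    return _unflatten(final, sizes), epochs


def _fit_lbfgs(sizes, X, y, X_val, y_val, hyper: Hyperparams, rng):
    theta0 = _flatten(init_params(sizes, rng))
    state = {"best": theta0.copy(), "best_val": np.inf, "since": 0, "iters": 0}

    def objective(theta):
        loss, grads = loss_and_grad(_unflatten(theta, sizes), X, y)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        return loss, _flatten(grads)

    def callback(theta):
        state["iters"] += 1
        if X_val is None:
            return
        val = float(np.mean((predict_net(_unflatten(theta, sizes), X_val) - y_val) ** 2))
        if val < state["best_val"] - 1e-12:
            state["best_val"], state["best"], state["since"] = val, theta.copy(), 0
        else:
            state["since"] += 1
            if state["since"] >= hyper.patience:
                raise StopIteration

    try:
        res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                       callback=callback, options={"maxiter": hyper.max_epochs})
        final = res.x
    except StopIteration:
        final = state["best"]
    if X_val is not None and state["best_val"] < np.inf:
        val_final = float(np.mean((predict_net(_unflatten(final, sizes), X_val) - y_val) ** 2))
        if state["best_val"] < val_final:
            final = state["best"]
    return _unflatten(final, sizes), state["iters"]


def train(records: pd.DataFrame, split, hyper: Hyperparams | None = None,
          seed: int = 0) -> TrainedModel:
    """Fit the 2x10 network on the training split of the valid records.

    ``split`` is either a :class:`SplitSpec` (resolved here) or an explicit
    ``(train_ids, test_ids)`` pair.  The feature pipeline and the inner
    early-stopping validation slice are derived from the training records
    only; the run is fully reproducible from ``seed``.
    """
    hyper = hyper or Hyperparams()
    hyper.validate()
    if isinstance(split, SplitSpec):
        train_ids, test_ids = split_records(records, split)
    else:
        train_ids, test_ids = list(split[0]), list(split[1])
    if not train_ids:
        raise ValueError("training split is empty")

    valid = records[records["valid"].astype(bool)].set_index("record_id", drop=False)
    train_df = valid.loc[train_ids]
    pipeline = FeaturePipeline().fit(train_df)
    X = pipeline.transform(train_df)
    y = train_df["delta_hb"].to_numpy(dtype=float)
    sizes = [X.shape[1], *hyper.hidden, 1]

    rng = np.random.Generator(np.random.PCG64(seed))
    metadata: dict = {"n_train": len(train_ids), "n_test": len(test_ids),
                      "solver": hyper.solver}

    if np.ptp(y) == 0.0:
        warnings.warn("constant training target; returning a bias-only fit")
        params = [(np.zeros((n_in, n_out)), np.zeros(n_out))
                  for n_in, n_out in zip(sizes[:-1], sizes[1:])]
        W_out, b_out = params[-1]
        params[-1] = (W_out, b_out + y[0])
        metadata.update(epochs_run=0, final_train_loss=0.0)
        return TrainedModel(sizes=sizes, params=params, pipeline=pipeline,
                            seed=seed, train_ids=train_ids, test_ids=test_ids,
                            metadata=metadata)

    n_val = int(round(hyper.val_fraction * len(y)))
    if n_val >= 1 and len(y) - n_val >= 2:
        order = rng.permutation(len(y))
        val_idx, fit_idx = order[:n_val], order[n_val:]
        X_fit, y_fit = X[fit_idx], y[fit_idx]
        X_val, y_val = X[val_idx], y[val_idx]
    else:
        X_fit, y_fit, X_val, y_val = X, y, None, None

    fit = _fit_lbfgs if hyper.solver == "lbfgs" else _fit_gd
    params, epochs = fit(sizes, X_fit, y_fit, X_val, y_val, hyper, rng)
    final_loss = float(np.mean((predict_net(params, X_fit) - y_fit) ** 2))
    metadata.update(epochs_run=int(epochs), final_train_loss=final_loss)
    return TrainedModel(sizes=sizes, params=params, pipeline=pipeline,
                        seed=seed, train_ids=train_ids, test_ids=test_ids,
                        metadata=metadata)


def predict(model: TrainedModel, records: pd.DataFrame) -> pd.DataFrame:
    """Predicted 3-month Hb change and implied absolute Hb for each record.

    Returns a DataFrame with ``record_id``, ``patient_id``,
    ``delta_hb_pred`` (g/dL) and ``hb_pred = hb_t + delta_hb_pred``.
    Prediction is a pure function of the frozen weights and scaler.
    """
    X = model.pipeline.transform(records)
    delta = predict_net(model.params, X)
    if not np.all(np.isfinite(delta)):
        raise FloatingPointError("non-finite prediction")
    return pd.DataFrame({
        "record_id": records["record_id"].to_numpy(),
        "patient_id": records["patient_id"].to_numpy(),
        "delta_hb_pred": delta,
        "hb_pred": records["hb_t"].to_numpy(dtype=float) + delta,
    })
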