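"""Survival estimators with a scikit-learn interface.

Every model predicts a single log relative hazard per subject and converts
it to an absolute survival time through a Breslow baseline hazard fitted on
its own training data:

* :class:`CoxPHSurvival` — linear Cox proportional hazards on tabular
  covariates (Newton-Raphson, Efron ties).
* :class:`DeepSurvMLP` — two-hidden-layer GELU perceptron trained with the
  Cox partial-likelihood loss (the DeepSurv formulation).
* :class:`ResNet2DSurvival` — residual network over coronal MIP images.
* :class:`ResNet3DSurvival` — 3-D residual network over PET volumes.
* :class:`MultimodalSurvival` — joint fusion: the 3-D ResNet's pooled
  feature vector concatenated with the MLP's last hidden activation under a
  single linear risk head, trained end-to-end.

``fit(X, y)`` takes outcomes ``y`` in any form accepted by
:func:`survfusion.survival.as_time_event` (records, ``(times, events)``,
structured array, DataFrame).  ``predict(X)`` returns predicted median
survival times in days (larger = better prognosis), so estimators compose
directly with the metrics in :mod:`survfusion.metrics`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn.resnet import RESNET2D_LAYERS, RESNET3D_LAYERS, ResNet, resnet2d, resnet3d
from .survival import (
    BaselineHazard,
    as_time_event,
    breslow_baseline,
    fit_cph,
    median_survival_time,
    survival_curve,
)

__all__ = [
    "MLP_WIDTHS",
    "ModelSpec",
    "MLPRiskNet",
    "MultimodalNet",
    "build_mlp",
    "build_resnet2d",
    "build_resnet3d",
    "build_multimodal",
    "build_model",
    "CoxPHSurvival",
    "DeepSurvMLP",
    "ResNet2DSurvival",
    "ResNet3DSurvival",
    "MultimodalSurvival",
    "save_checkpoint",
    "load_checkpoint",
]

MLP_WIDTHS = (32, 64, 128)


# ---------------------------------------------------------------------------
# Network constructors
# ---------------------------------------------------------------------------


class MLPRiskNet(nn.Module):
    """Two hidden GELU layers of equal width, linear scalar risk head."""

    def __init__(self, input_dim: int, hidden_width: int, rng: np.random.Generator):
        super().__init__()
        self.input_dim = input_dim
        self.hidden_width = hidden_width
        self.fc1 = nn.Linear(input_dim, hidden_width, rng)
        self.fc2 = nn.Linear(hidden_width, hidden_width, rng)
        self.act = nn.GELU()
        self.head = nn.Linear(hidden_width, 1, rng)

    def hidden(self, x: nn.Tensor) -> nn.Tensor:
        """Last hidden activation (the representation used for fusion)."""
        return self.act(self.fc2(self.act(self.fc1(x))))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.head(self.hidden(x))


class MultimodalNet(nn.Module):
    """Joint fusion of a 3-D ResNet branch and a clinical MLP branch."""

    def __init__(self, image_net: ResNet, clinical_net: MLPRiskNet, rng):
        super().__init__()
        self.image = image_net
        self.clinical = clinical_net
        self.fused_dim = image_net.feature_dim + clinical_net.hidden_width
        self.head = nn.Linear(self.fused_dim, 1, rng)

    def forward(self, clinical: nn.Tensor, volume: nn.Tensor) -> nn.Tensor:
        if clinical is None or volume is None:
            raise ValueError("multimodal forward requires both modalities")
        fused = nn.concat(
            [self.image.features(volume), self.clinical.hidden(clinical)], axis=1
        )
        return self.head(fused)


def build_mlp(input_dim: int, hidden_width: int = 64, seed: int = 0) -> MLPRiskNet:
    if input_dim < 1:
        raise ValueError("input_dim must be at least 1")
    if hidden_width not in MLP_WIDTHS:
        raise ValueError(f"hidden_width must be one of {MLP_WIDTHS}, got {hidden_width}")
    return MLPRiskNet(input_dim, hidden_width, np.random.default_rng(seed))


def build_resnet2d(layers: int, in_channels: int = 1, seed: int = 0) -> ResNet:
    return resnet2d(layers, np.random.default_rng(seed), in_channels)


def build_resnet3d(layers: int, in_channels: int = 1, seed: int = 0) -> ResNet:
    return resnet3d(layers, np.random.default_rng(seed), in_channels)


@dataclass(frozen=True)
class ModelSpec:
    """Serializable description of a network architecture.

    ``kind`` is one of ``mlp``, ``resnet2d``, ``resnet3d``, ``multimodal``.
    A multimodal spec embeds one ``resnet3d`` spec and one ``mlp`` spec.
    """

    kind: str
    input_dim: Optional[int] = None
    hidden_width: Optional[int] = None
    depth: Optional[int] = None
    in_channels: int = 1
    resnet3d: Optional["ModelSpec"] = None
    mlp: Optional["ModelSpec"] = None

    def __post_init__(self):
        kinds = ("mlp", "resnet2d", "resnet3d", "multimodal")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind == "mlp" and self.hidden_width not in MLP_WIDTHS:
            raise ValueError(f"mlp hidden_width must be in {MLP_WIDTHS}")
        if self.kind == "resnet2d" and self.depth not in RESNET2D_LAYERS:
            raise ValueError(f"resnet2d depth must be in {sorted(RESNET2D_LAYERS)}")
        if self.kind == "resnet3d" and self.depth not in RESNET3D_LAYERS:
            raise ValueError(f"resnet3d depth must be in {sorted(RESNET3D_LAYERS)}")
        if self.kind == "multimodal":
            if self.resnet3d is None or self.mlp is None:
                raise ValueError("multimodal spec embeds a resnet3d and an mlp spec")
            if self.resnet3d.kind != "resnet3d" or self.mlp.kind != "mlp":
                raise ValueError("multimodal sub-specs have the wrong kinds")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if "resnet3d" in d and isinstance(d["resnet3d"], dict):
            d["resnet3d"] = cls.from_dict(d["resnet3d"])
        if "mlp" in d and isinstance(d["mlp"], dict):
            d["mlp"] = cls.from_dict(d["mlp"])
        return cls(**d)


def build_multimodal(
    resnet3d_spec: ModelSpec | None = None,
    mlp_spec: ModelSpec | None = None,
    seed: int = 0,
) -> MultimodalNet:
    """Construct the joint-fusion network.

    Defaults to the best-performing unimodal configurations: ResNet3D-34 for
    the image branch and the 64-node MLP for the clinical branch.
    """
    if resnet3d_spec is None:
        resnet3d_spec = ModelSpec(kind="resnet3d", depth=34)
    if mlp_spec is None:
        mlp_spec = ModelSpec(kind="mlp", input_dim=17, hidden_width=64)
    rng = np.random.default_rng(seed)
    image = resnet3d(resnet3d_spec.depth, rng, resnet3d_spec.in_channels)
    clinical = MLPRiskNet(mlp_spec.input_dim, mlp_spec.hidden_width, rng)
    return MultimodalNet(image, clinical, rng)


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Module:
    if spec.kind == "mlp":
        return build_mlp(spec.input_dim, spec.hidden_width, seed)
    if spec.kind == "resnet2d":
        return build_resnet2d(spec.depth, spec.in_channels, seed)
    if spec.kind == "resnet3d":
        return build_resnet3d(spec.depth, spec.in_channels, seed)
    return build_multimodal(spec.resnet3d, spec.mlp, seed)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class _BaseSurvivalEstimator(BaseEstimator):
    """Shared fit/predict plumbing for all survival estimators."""

    horizon_days: float

    def _fit_baseline(self, X, times, events) -> None:
        risks = self.predict_risk(X)
        self.baseline_hazard_: BaselineHazard = breslow_baseline(risks, (times, events))

    def predict_risk(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict_survival_function(self, X) -> list:
        risks = self.predict_risk(X)
        return [survival_curve(self.baseline_hazard_, h) for h in risks]

    def predict(self, X) -> np.ndarray:
        """Predicted median survival time (days) per subject."""
        return np.array(
            [
                median_survival_time(c, self.horizon_days).time
                for c in self.predict_survival_function(X)
            ]
        )

    def score(self, X, y) -> float:
        from .metrics import concordance_index

        return concordance_index(y, self.predict(X)).value


class CoxPHSurvival(_BaseSurvivalEstimator):
    """Linear Cox proportional hazards on an encoded design matrix."""

    def __init__(self, tol: float = 1e-9, max_iter: int = 100, horizon_days: float = 3650.0):
        self.tol = tol
        self.max_iter = max_iter
        self.horizon_days = horizon_days

    def fit(self, X, y, column_names=None):
        X = np.asarray(X, dtype=float)
        times, events = as_time_event(y)
        # center covariates for numerical stability; shift-invariant model
        self.center_ = X.mean(axis=0)
        self.fit_ = fit_cph(
            X - self.center_,
            (times, events),
            tol=self.tol,
            max_iter=self.max_iter,
            column_names=column_names,
        )
        self.coef_ = self.fit_.coefficients
        self._fit_baseline(X, times, events)
        return self

    def predict_risk(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.center_) @ self.coef_


class _BaseDeepSurvival(_BaseSurvivalEstimator):
    """Common training plumbing for the neural estimators."""

    def __init__(
        self,
        learning_rate: float = 1e-4,
        batch_size: int = 125,
        max_epochs: int = 200,
        patience: int = 3,
        l2_weight: float = 1e-4,
        validation_fraction: float = 0.2,
        random_state: int = 0,
        horizon_days: float = 3650.0,
        eval_batch_size: int = 32,
    ):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.l2_weight = l2_weight
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.horizon_days = horizon_days
        self.eval_batch_size = eval_batch_size

    # subclasses implement:
    def _build_network(self, X, rng) -> nn.Module:
        raise NotImplementedError

    def _prepare_fit_inputs(self, X) -> object:
        """Fit any input transform (e.g. the clinical scaler) and return
        the transformed training inputs."""
        raise NotImplementedError

    def _transform_inputs(self, X) -> object:
        raise NotImplementedError

    def _batch_tensors(self, prepared, idx) -> tuple:
        raise NotImplementedError

    def fit(self, X, y):
        from .training import TrainConfig, train_network

        times, events = as_time_event(y)
        rng = np.random.default_rng(self.random_state)
        prepared = self._prepare_fit_inputs(X)
        self.network_ = self._build_network(X, rng)
        config = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            l2_weight=self.l2_weight,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
        )
        self.history_ = train_network(
            self.network_,
            lambda idx: self._batch_tensors(prepared, idx),
            times,
            events,
            config,
            rng,
        )
        self._fit_baseline(X, times, events)
        return self

    def predict_risk(self, X) -> np.ndarray:
        prepared = self._transform_inputs(X)
        n = self._n_subjects(prepared)
        self.network_.eval()
        out = np.empty(n, dtype=float)
        with nn.no_grad():
            for start in range(0, n, self.eval_batch_size):
                idx = np.arange(start, min(start + self.eval_batch_size, n))
                h = self.network_(*self._batch_tensors(prepared, idx))
                out[idx] = h.data.reshape(-1)
        return out

    @staticmethod
    def _n_subjects(prepared) -> int:
        if isinstance(prepared, dict):
            return len(next(iter(prepared.values())))
        return len(prepared)


class DeepSurvMLP(_BaseDeepSurvival):
    """DeepSurv: a Cox-loss MLP over clinical covariates.

    Covariates are standardized with mean/scale computed on the training
    data only (stored as ``scaler_mean_`` / ``scaler_scale_``).
    """

    def __init__(
        self,
        hidden_width: int = 64,
        standardize: bool = True,
        learning_rate: float = 1e-4,
        batch_size: int = 125,
        max_epochs: int = 200,
        patience: int = 3,
        l2_weight: float = 1e-4,
        validation_fraction: float = 0.2,
        random_state: int = 0,
        horizon_days: float = 3650.0,
        eval_batch_size: int = 256,
    ):
        super().__init__(
            learning_rate,
            batch_size,
            max_epochs,
            patience,
            l2_weight,
            validation_fraction,
            random_state,
            horizon_days,
            eval_batch_size,
        )
        self.hidden_width = hidden_width
        self.standardize = standardize

    def _build_network(self, X, rng):
        X = np.asarray(X)
        if self.hidden_width not in MLP_WIDTHS:
            raise ValueError(f"hidden_width must be one of {MLP_WIDTHS}")
        return MLPRiskNet(X.shape[1], self.hidden_width, rng)

    def _prepare_fit_inputs(self, X):
        X = np.asarray(X, dtype=np.float32)
        if self.standardize:
            self.scaler_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.scaler_scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.scaler_mean_ = np.zeros(X.shape[1], dtype=np.float32)
            self.scaler_scale_ = np.ones(X.shape[1], dtype=np.float32)
        return (X - self.scaler_mean_) / self.scaler_scale_

    def _transform_inputs(self, X):
        X = np.asarray(X, dtype=np.float32)
        return (X - self.scaler_mean_) / self.scaler_scale_

    def _batch_tensors(self, prepared, idx):
        return (nn.Tensor(prepared[idx]),)


class _BaseImageSurvival(_BaseDeepSurvival):
    """Shared input handling for the image estimators (adds channel axis)."""

    _nd: int

    def _prepare_fit_inputs(self, X):
        return self._transform_inputs(X)

    def _transform_inputs(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == self._nd + 1:  # (N, *spatial) -> add channel axis
            X = X[:, None]
        if X.ndim != self._nd + 2:
            raise ValueError(
                f"expected (N, *spatial) or (N, C, *spatial) with {self._nd} "
                f"spatial dims, got shape {X.shape}"
            )
        return X

    def _batch_tensors(self, prepared, idx):
        return (nn.Tensor(prepared[idx]),)


class ResNet2DSurvival(_BaseImageSurvival):
    """Residual network over coronal MIP images, Cox partial-likelihood loss."""

    _nd = 2

    def __init__(
        self,
        depth: int = 50,
        in_channels: int = 1,
        learning_rate: float = 1e-4,
        batch_size: int = 6,
        max_epochs: int = 200,
        patience: int = 3,
        l2_weight: float = 1e-4,
        validation_fraction: float = 0.2,
        random_state: int = 0,
        horizon_days: float = 3650.0,
        eval_batch_size: int = 32,
    ):
        super().__init__(
            learning_rate,
            batch_size,
            max_epochs,
            patience,
            l2_weight,
            validation_fraction,
            random_state,
            horizon_days,
            eval_batch_size,
        )
        self.depth = depth
        self.in_channels = in_channels

    def _build_network(self, X, rng):
        return resnet2d(self.depth, rng, self.in_channels)


class ResNet3DSurvival(_BaseImageSurvival):
    """3-D residual network over PET volumes, Cox partial-likelihood loss."""

    _nd = 3

    def __init__(
        self,
        depth: int = 34,
        in_channels: int = 1,
        learning_rate: float = 1e-4,
        batch_size: int = 6,
        max_epochs: int = 200,
        patience: int = 3,
        l2_weight: float = 1e-4,
        validation_fraction: float = 0.2,
        random_state: int = 0,
        horizon_days: float = 3650.0,
        eval_batch_size: int = 16,
    ):
        super().__init__(
            learning_rate,
            batch_size,
            max_epochs,
            patience,
            l2_weight,
            validation_fraction,
            random_state,
            horizon_days,
            eval_batch_size,
        )
        self.depth = depth
        self.in_channels = in_channels

    def _build_network(self, X, rng):
        return resnet3d(self.depth, rng, self.in_channels)


class MultimodalSurvival(_BaseDeepSurvival):
    """Joint-fusion model over ``{"clinical": (n, p), "volume": (n, *vol)}``.

    The 3-D ResNet pooled features and the MLP's last hidden activation are
    concatenated under one linear risk head; the whole graph trains
    end-to-end.  Clinical covariates are standardized on the training data.
    """

    def __init__(
        self,
        resnet_depth: int = 34,
        mlp_hidden_width: int = 64,
        in_channels: int = 1,
        learning_rate: float = 1e-4,
        batch_size: int = 6,
        max_epochs: int = 200,
        patience: int = 3,
        l2_weight: float = 1e-4,
        validation_fraction: float = 0.2,
        random_state: int = 0,
        horizon_days: float = 3650.0,
        eval_batch_size: int = 16,
    ):
        super().__init__(
            learning_rate,
            batch_size,
            max_epochs,
            patience,
            l2_weight,
            validation_fraction,
            random_state,
            horizon_days,
            eval_batch_size,
        )
        self.resnet_depth = resnet_depth
        self.mlp_hidden_width = mlp_hidden_width
        self.in_channels = in_channels

    @staticmethod
    def _check_modalities(X) -> tuple[np.ndarray, np.ndarray]:
        if not isinstance(X, dict) or "clinical" not in X or "volume" not in X:
            raise ValueError(
                'multimodal input must be a dict with "clinical" and "volume" keys'
            )
        return X["clinical"], X["volume"]

    def _build_network(self, X, rng):
        clin, _ = self._check_modalities(X)
        image = resnet3d(self.resnet_depth, rng, self.in_channels)
        clinical = MLPRiskNet(
            np.asarray(clin).shape[1], self.mlp_hidden_width, rng
        )
        return MultimodalNet(image, clinical, rng)

    def _prepare_fit_inputs(self, X):
        clin, vol = self._check_modalities(X)
        clin = np.asarray(clin, dtype=np.float32)
        self.scaler_mean_ = clin.mean(axis=0)
        scale = clin.std(axis=0)
        self.scaler_scale_ = np.where(scale > 0, scale, 1.0)
        return self._transform_inputs(X)

    def _transform_inputs(self, X):
        clin, vol = self._check_modalities(X)
        clin = np.asarray(clin, dtype=np.float32)
        vol = np.asarray(vol, dtype=np.float32)
        if vol.ndim == 4:
            vol = vol[:, None]
        if len(clin) != len(vol):
            raise ValueError("clinical and volume inputs are misaligned")
        return {
            "clinical": (clin - self.scaler_mean_) / self.scaler_scale_,
            "volume": vol,
        }

    def _batch_tensors(self, prepared, idx):
        return (
            nn.Tensor(prepared["clinical"][idx]),
            nn.Tensor(prepared["volume"][idx]),
        )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

_ESTIMATOR_CLASSES = {}
for _cls in (CoxPHSurvival, DeepSurvMLP, ResNet2DSurvival, ResNet3DSurvival, MultimodalSurvival):
    _ESTIMATOR_CLASSES[_cls.__name__] = _cls


def save_checkpoint(estimator, path) -> None:
    """Save a fitted estimator (params + weights + baseline) as .npz."""
    arrays = {}
    meta = {
        "class": type(estimator).__name__,
        "params": estimator.get_params(),
    }
    arrays["baseline_times"] = estimator.baseline_hazard_.event_times
    arrays["baseline_hazard"] = estimator.baseline_hazard_.cumulative_hazard
    if isinstance(estimator, CoxPHSurvival):
        arrays["coef"] = estimator.coef_
        arrays["center"] = estimator.center_
        arrays["se"] = estimator.fit_.standard_errors
        meta["log_likelihood"] = estimator.fit_.log_likelihood
        meta["converged"] = bool(estimator.fit_.converged)
    else:
        for key, value in estimator.network_.state_dict().items():
            arrays["state//" + key] = value
        for attr in ("scaler_mean_", "scaler_scale_"):
            if hasattr(estimator, attr):
                arrays[attr] = getattr(estimator, attr)
        if hasattr(estimator, "history_"):
            meta["history"] = {
                k: v for k, v in estimator.history_.items() if k != "config"
            }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, default=float).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Restore an estimator saved by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        cls = _ESTIMATOR_CLASSES[meta["class"]]
        est = cls(**meta["params"])
        est.baseline_hazard_ = BaselineHazard(
            data["baseline_times"], data["baseline_hazard"]
        )
        if cls is CoxPHSurvival:
            from .survival import CoxFit

            est.coef_ = data["coef"]
            est.center_ = data["center"]
            est.fit_ = CoxFit(
                coefficients=data["coef"],
                standard_errors=data["se"],
                log_likelihood=meta["log_likelihood"],
                converged=meta["converged"],
            )
        else:
            state = {
                key.split("//", 1)[1]: data[key]
                for key in data.files
                if key.startswith("state//")
            }
            # rebuild the network; input_dim is recoverable from the weights
            rng = np.random.default_rng(est.random_state)
            if cls is DeepSurvMLP:
                input_dim = state["param:fc1.weight"].shape[1]
                est.network_ = MLPRiskNet(input_dim, est.hidden_width, rng)
            elif cls is ResNet2DSurvival:
                est.network_ = resnet2d(est.depth, rng, est.in_channels)
            elif cls is ResNet3DSurvival:
                est.network_ = resnet3d(est.depth, rng, est.in_channels)
            else:
                input_dim = state["param:clinical.fc1.weight"].shape[1]
                image = resnet3d(est.resnet_depth, rng, est.in_channels)
                clinical = MLPRiskNet(input_dim, est.mlp_hidden_width, rng)
                est.network_ = MultimodalNet(image, clinical, rng)
            est.network_.load_state_dict(state)
            est.network_.eval()
            for attr in ("scaler_mean_", "scaler_scale_"):
                if attr in data.files:
                    setattr(est, attr, data[attr])
        if "history" in meta:
            est.history_ = meta["history"]
    return est
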