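"""Anomaly transformer for seven-step creatinine-eGFR windows.

An unsupervised reconstruction model whose attention layers carry two
association maps per head: a data-driven series association S (softmax
self-attention) and a prior association P built from a Gaussian kernel over
inter-step distance with a learnable per-position scale sigma. The per-step
association discrepancy — symmetric KL divergence between the P and S rows,
averaged over layers and heads — combines with the reconstruction error into
a per-step anomaly score. Training is minimax: each batch update combines a
prior-side loss pulling P toward the (stop-gradient) series association and
a weaker series-side loss pushing S away from the (stop-gradient) prior,
both on top of the reconstruction objective (see ModelConfig.lambda_disc
and ModelConfig.lambda_push).

The final-step score s_T, thresholded at a fixed quantile of the training
distribution (tau at the 95th percentile by default), drives the composite
anomaly-detected-AKI rule downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, relu, softmax

__all__ = [
    "ModelConfig",
    "Threshold",
    "AnomalyScoreVector",
    "AnomalyTransformer",
    "association_discrepancy",
    "combine_scores",
    "calibrate_threshold",
    "TrainingError",
]

CHECKPOINT_SCHEMA = "trajaki-anomaly-model-v1"
KL_EPS = 1e-8          # probability floor before logarithms
SIGMA_MIN = 1.0        # bounds on the Gaussian prior scale (steps); the upper
SIGMA_MAX = 3.0        # bound keeps rows informative and the KL terms finite


class TrainingError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    Defaults are the published architecture's settings scaled down for
    seven-step, two-variable windows.
    """

    window_len: int = 7
    n_vars: int = 2
    d_model: int = 32
    n_heads: int = 2
    n_layers: int = 2
    lambda_disc: float = 3.0   # discrepancy weight, phase A (prior -> series)
    lambda_push: float = 0.05   # discrepancy weight, phase B (series away from prior)
    lr: float = 2e-4
    batch_size: int = 256
    max_epochs: int = 40
    patience: int = 5
    denoise_sd: float = 0.0   # optional training-time input corruption (z units)
    seed: int = 0

    def validate(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.lambda_disc <= 0:
            raise ValueError("lambda_disc must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class Threshold:
    """Fixed decision threshold: the q-th percentile of training s_T."""

    tau: float
    q: float = 95.0
    source: str = "train"


@dataclass
class AnomalyScoreVector:
    """Per-step anomaly scores for a batch of windows (arrays share axis 0)."""

    per_step_score: np.ndarray   # (n, T)
    s_last: np.ndarray           # (n,)
    recon_error: np.ndarray      # (n, T)
    ass_dis: np.ndarray          # (n, T)


# ---------------------------------------------------------------------------
# pure scoring / discrepancy formulas (shared by the graph and by tests)

def _row_sym_kl(p: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Rowwise symmetric KL over the last axis with epsilon flooring."""
    p = np.maximum(p, KL_EPS)
    s = np.maximum(s, KL_EPS)
    return ((p - s) * (np.log(p) - np.log(s))).sum(axis=-1)


def association_discrepancy(priors, series) -> np.ndarray:
    """Per-step association discrepancy from per-layer association maps.

    `priors`/`series` are sequences of row-stochastic arrays shaped
    (..., n_heads, T, T). Returns the mean over layers and heads of the
    rowwise symmetric KL divergence, shaped (..., T). Zero iff P == S.
    """
    per_layer = [_row_sym_kl(p, s).mean(axis=-2) for p, s in zip(priors, series)]
    return np.mean(per_layer, axis=0)


def combine_scores(ass_dis: np.ndarray, recon_error: np.ndarray) -> np.ndarray:
    """Anomaly score: softmax over steps of (-AssDis), times per-step recon error."""
    a = -np.asarray(ass_dis, dtype=float)
    a = a - a.max(axis=-1, keepdims=True)
    w = np.exp(a)
    w /= w.sum(axis=-1, keepdims=True)
    return w * np.asarray(recon_error, dtype=float)


def calibrate_threshold(train_s_last, q: float = 95.0) -> Threshold:
    """Fixed threshold at the q-th percentile (linear interpolation) of s_T.

    Calibrated once on training scores and reused everywhere afterwards; no
    recalibration for external data.
    """
    scores = np.asarray(train_s_last, dtype=float)
    if scores.size < 20:
        raise ValueError("need at least 20 training scores to calibrate")
    if not 0.0 < q < 100.0:
        raise ValueError("percentile q must be in (0, 100)")
    tau = float(np.percentile(scores, q, method="linear"))
    return Threshold(tau=tau, q=q)


# ---------------------------------------------------------------------------
# model internals

def _init_params(cfg: ModelConfig, rng: np.random.Generator) -> dict:
    d, T, V, H = cfg.d_model, cfg.window_len, cfg.n_vars, cfg.n_heads

    def lin(n_in, n_out):
        return rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out))

    p = {"W_in": lin(V, d), "b_in": np.zeros(d), "pos": 0.02 * rng.standard_normal((T, d)),
         "W_out": lin(d, V), "b_out": np.zeros(V)}
    for l in range(cfg.n_layers):
        p[f"Wq{l}"] = lin(d, d)
        p[f"Wk{l}"] = lin(d, d)
        p[f"Wv{l}"] = lin(d, d)
        p[f"Wo{l}"] = lin(d, d)
        p[f"bo{l}"] = np.zeros(d)
        p[f"Wsig{l}"] = lin(d, H)
        p[f"bsig{l}"] = np.full(H, 1.0)  # start sigma in the upper half of its range
        p[f"g1_{l}"] = np.ones(d)
        p[f"b1_{l}"] = np.zeros(d)
        p[f"g2_{l}"] = np.ones(d)
        p[f"b2_{l}"] = np.zeros(d)
        p[f"Wf1{l}"] = lin(d, 2 * d)
        p[f"bf1{l}"] = np.zeros(2 * d)
        p[f"Wf2{l}"] = lin(2 * d, d)
        p[f"bf2{l}"] = np.zeros(d)
    return p


def _layer_norm(h: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    mu = h.mean(axis=-1, keepdims=True)
    xc = h - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + 1e-6) ** 0.5 * gamma + beta


def _sym_kl_rows(p: Tensor, s: Tensor) -> Tensor:
    pf = p.clamp_min(KL_EPS)
    sf = s.clamp_min(KL_EPS)
    return ((pf - sf) * (pf.log() - sf.log())).sum(axis=-1)


class AnomalyTransformer:
    """Trainable window-level anomaly detector.

    Typical use::

        model = AnomalyTransformer(ModelConfig(max_epochs=20, seed=1))
        model.fit(train_values, val_values)        # (n, 7, 2) arrays
        scores = model.score(test_values)          # AnomalyScoreVector
        thr = calibrate_threshold(model.score(train_values).s_last, q=95)
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.config.validate()
        rng = np.random.default_rng(self.config.seed)
        self._weights = _init_params(self.config, rng)
        self.norm_mean: np.ndarray | None = None
        self.norm_std: np.ndarray | None = None
        self.threshold: Threshold | None = None
        self.history: dict = {"train_loss": [], "val_loss": []}

    # -- forward -----------------------------------------------------------
    def _params(self, trainable: bool) -> dict:
        return {k: Tensor(v, requires_grad=trainable) for k, v in self._weights.items()}

    def forward(self, x: np.ndarray, params: dict | None = None):
        """Reconstruct a normalized batch; returns (recon, priors, series).

        `x` is (B, T, V) already normalized. `priors`/`series` are per-layer
        (B, H, T, T) row-stochastic association maps (Tensors).
        """
        cfg = self.config
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite model input")
        if params is None:
            params = self._params(trainable=False)
        B, T, V = x.shape
        H = cfg.n_heads
        dh = cfg.d_model // H
        dist2 = (np.arange(T)[:, None] - np.arange(T)[None, :]).astype(float) ** 2

        h = Tensor(x) @ params["W_in"] + params["b_in"] + params["pos"]
        priors, series = [], []
        for l in range(cfg.n_layers):
            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

            q = heads(h @ params[f"Wq{l}"])
            k = heads(h @ params[f"Wk{l}"])
            v = heads(h @ params[f"Wv{l}"])
            S = softmax(q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh)), axis=-1)

            sigma = (h @ params[f"Wsig{l}"] + params[f"bsig{l}"]).sigmoid() \
                * (SIGMA_MAX - SIGMA_MIN) + SIGMA_MIN
            sigma = sigma.transpose(0, 2, 1).reshape(B, H, T, 1)      # per-position scale
            P_un = (Tensor(-0.5 * dist2) / (sigma * sigma)).exp()
            P = P_un / P_un.sum(axis=-1, keepdims=True)

            priors.append(P)
            series.append(S)
            attn = (S @ v).transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
            h = _layer_norm(h + attn @ params[f"Wo{l}"] + params[f"bo{l}"],
                            params[f"g1_{l}"], params[f"b1_{l}"])
            ffn = relu(h @ params[f"Wf1{l}"] + params[f"bf1{l}"]) @ params[f"Wf2{l}"] + params[f"bf2{l}"]
            h = _layer_norm(h + ffn, params[f"g2_{l}"], params[f"b2_{l}"])
        recon = h @ params["W_out"] + params["b_out"]
        return recon, priors, series

    # -- training ------------------------------------------------------------
    def _normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mean) / self.norm_std

    @staticmethod
    def _graph_assdis(priors, series, detach: str) -> Tensor:
        """Mean-over-batch/step association discrepancy with one side detached."""
        total = None
        n_maps = 0
        for P, S in zip(priors, series):
            Pd = P.detach() if detach == "prior" else P
            Sd = S.detach() if detach == "series" else S
            kl = _sym_kl_rows(Pd, Sd).mean(axis=1)  # mean over heads -> (B, T)
            total = kl if total is None else total + kl
            n_maps += 1
        return (total * (1.0 / n_maps)).mean()

    def fit(self, train_values: np.ndarray, val_values: np.ndarray):
        """Minimax training with early stopping on validation reconstruction loss.

        `train_values`/`val_values` are raw (n, 7, 2) window arrays; labels are
        never seen. Per-variable z-normalization statistics are computed from
        the training windows and frozen. Returns self.
        """
        cfg = self.config
        if len(train_values) == 0 or len(val_values) == 0:
            raise ValueError("train and validation sets must be non-empty")
        self.norm_mean = train_values.reshape(-1, cfg.n_vars).mean(axis=0)
        self.norm_std = train_values.reshape(-1, cfg.n_vars).std(axis=0)
        self.norm_std = np.where(self.norm_std < 1e-9, 1.0, self.norm_std)
        xtr = self._normalize(train_values)
        xval = self._normalize(val_values)

        rng = np.random.default_rng(cfg.seed + 1)
        adam_m = {k: np.zeros_like(v) for k, v in self._weights.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self._weights.items()}
        step = 0

        def adam_update(params):
            nonlocal step
            step += 1
            b1, b2, eps = 0.9, 0.999, 1e-8
            for kname, t in params.items():
                if t.grad is None:
                    continue
                g = t.grad
                adam_m[kname] = b1 * adam_m[kname] + (1 - b1) * g
                adam_v[kname] = b2 * adam_v[kname] + (1 - b2) * g * g
                mhat = adam_m[kname] / (1 - b1 ** step)
                vhat = adam_v[kname] / (1 - b2 ** step)
                self._weights[kname] = self._weights[kname] - cfg.lr * mhat / (np.sqrt(vhat) + eps)

        best_val = np.inf
        best_weights = {k: v.copy() for k, v in self._weights.items()}
        bad_epochs = 0
        n = len(xtr)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                xb = xtr[order[start:start + cfg.batch_size]]
                xin = xb if cfg.denoise_sd == 0 else xb + rng.normal(
                    0.0, cfg.denoise_sd, size=xb.shape)
                # one forward, both minimax phases, one update: phase A pulls
                # the prior toward the (detached) series association, phase B
                # pushes the series association away from the (detached) prior;
                # both minimize reconstruction error.
                params = self._params(trainable=True)
                recon, priors, series = self.forward(xin, params)
                rec_loss = ((recon - Tensor(xb)) ** 2).mean()
                loss_a = self._graph_assdis(priors, series, detach="series")
                loss_b = self._graph_assdis(priors, series, detach="prior")
                total = rec_loss + loss_a * cfg.lambda_disc - loss_b * cfg.lambda_push
                total.backward()
                adam_update(params)
                if not np.isfinite(total.data):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch}, batch {n_batches}")
                epoch_loss += float(rec_loss.data)
                n_batches += 1
            val_loss = self._recon_mse(xval)
            self.history["train_loss"].append(epoch_loss / max(1, n_batches))
            self.history["val_loss"].append(val_loss)
            if not np.isfinite(val_loss):
                raise TrainingError(f"non-finite validation loss at epoch {epoch}")
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_weights = {k: v.copy() for k, v in self._weights.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break
        self._weights = best_weights
        return self

    def _recon_mse(self, x_norm: np.ndarray) -> float:
        total, count = 0.0, 0
        for start in range(0, len(x_norm), self.config.batch_size):
            xb = x_norm[start:start + self.config.batch_size]
            recon, _, _ = self.forward(xb)
            total += float(((recon.data - xb) ** 2).sum())
            count += xb.size
        return total / max(1, count)

    # -- scoring ---------------------------------------------------------------
    def score(self, values: np.ndarray, batch_size: int | None = None) -> AnomalyScoreVector:
        """Per-step anomaly scores for raw (n, 7, 2) windows.

        score_i = softmax_over_steps(-AssDis)_i * recon_error_i, where the
        reconstruction error is the squared error averaged over the two
        channels. Batch scoring equals per-window scoring elementwise.
        """
        if self.norm_mean is None:
            raise RuntimeError("model is not fitted")
        bs = batch_size or self.config.batch_size
        outs = []
        for start in range(0, len(values), bs):
            xb = self._normalize(values[start:start + bs])
            recon, priors, series = self.forward(xb)
            rec_err = ((recon.data - xb) ** 2).mean(axis=-1)          # (B, T)
            assdis = association_discrepancy([p.data for p in priors],
                                             [s.data for s in series])  # (B, T)
            outs.append((rec_err, assdis))
        if not outs:
            empty = np.zeros((0, self.config.window_len))
            return AnomalyScoreVector(empty, np.zeros(0), empty.copy(), empty.copy())
        rec_err = np.concatenate([o[0] for o in outs])
        assdis = np.concatenate([o[1] for o in outs])
        per_step = combine_scores(assdis, rec_err)
        return AnomalyScoreVector(per_step, per_step[:, -1].copy(), rec_err, assdis)

    # -- persistence -------------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive checkpoint: weights, config, normalization, threshold."""
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "config": asdict(self.config),
            "threshold": asdict(self.threshold) if self.threshold else None,
        }
        arrays = {f"w__{k}": v for k, v in self._weights.items()}
        if self.norm_mean is not None:
            arrays["norm_mean"] = self.norm_mean
            arrays["norm_std"] = self.norm_std
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "AnomalyTransformer":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise ValueError(
                    f"checkpoint schema {meta.get('schema')!r} is not {CHECKPOINT_SCHEMA!r}")
            model = cls(ModelConfig(**meta["config"]))
            model._weights = {k[3:]: data[k] for k in data.files if k.startswith("w__")}
            if "norm_mean" in data.files:
                model.norm_mean = data["norm_mean"]
                model.norm_std = data["norm_std"]
            if meta.get("threshold"):
                model.threshold = Threshold(**meta["threshold"])
        return model
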