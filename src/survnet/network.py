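"""The multi-task survival network: forward computation and backprop.

Architecture: a shared tanh encoder (input -> 64), a linear reconstruction
decoder (64 -> input), batch normalization of the encoding, a tanh hidden
layer (64 -> 32), a logistic survival-classification head (32 -> 1) and a
linear Cox head (32 -> 1) fed through dropout.  With gating enabled the
prognosis index is the elementwise product ``p_x = a_p * a_c`` — the
classification head's survival probability modulates the Cox head's log
hazard.  Note this shrinks *negative* log-hazards toward 0 as ``a_c -> 0``,
which raises the index of patients predicted to die; the product form is
implemented exactly as defined.

Everything is plain numpy: parameters live in a dict of arrays, gradients
are computed by a hand-written reverse pass (finite-difference checked in
the test suite), and checkpoints are JSON so they survive text-only
round-trips.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .data_model import CohortSchema, CovariateSpec, StandardizationStats

#: weight-matrix parameter names (weight decay applies to these only)
WEIGHT_KEYS = ("We", "Wd", "W3", "Wc", "Wp")

BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ArchitectureConfig:
    input_dim: int = 9
    encoder_units: int = 64
    hidden_units: int = 32
    use_batchnorm: bool = True
    dropout_rate: float = 0.0
    use_reconstruction: bool = True
    use_classification: bool = True
    use_gating: bool = True
    bias_terms: bool = True
    batchnorm_epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.encoder_units < 1 or self.hidden_units < 1:
            raise ValueError("all unit counts must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.batchnorm_epsilon <= 0:
            raise ValueError("batchnorm_epsilon must be positive")
        if self.use_gating and not self.use_classification:
            raise ValueError("use_gating requires use_classification")


@dataclass
class NetworkOutputs:
    """Per-batch forward results; intermediate activations exposed for tests."""

    x_star: Optional[np.ndarray]
    a_c: Optional[np.ndarray]
    a_p: np.ndarray
    p_x: np.ndarray
    a2: np.ndarray
    a3: np.ndarray
    a4: np.ndarray


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SurvNetModel:
    """Parameter container plus forward/backward passes.

    ``mode`` is either ``"training"`` (batch statistics, dropout active) or
    ``"inference"`` (running statistics, dropout off); forward in inference
    mode is deterministic and batch-size invariant.
    """

    def __init__(self, architecture: ArchitectureConfig, params: dict,
                 bn_state: dict):
        self.architecture = architecture
        self.params = params
        self.bn_state = bn_state
        self.mode = "training"

    # -- construction -----------------------------------------------------

    @classmethod
    def initialize(cls, arch: ArchitectureConfig, seed: int) -> "SurvNetModel":
        """Uniform fan-in initialization, deterministic given ``seed``.

        Weights and biases of a layer with fan-in ``m`` are drawn from
        U(-1/sqrt(m), 1/sqrt(m)); batch-norm scale starts at 1, shift at 0.
        """
        rng = np.random.default_rng(seed)

        def uniform(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        p, h1, h2 = arch.input_dim, arch.encoder_units, arch.hidden_units
        params: dict[str, np.ndarray] = {}
        params["We"] = uniform((p, h1), p)
        if arch.bias_terms:
            params["be"] = uniform((h1,), p)
        if arch.use_reconstruction:
            params["Wd"] = uniform((h1, p), h1)
            if arch.bias_terms:
                params["bd"] = uniform((p,), h1)
        if arch.use_batchnorm:
            params["bn_gamma"] = np.ones(h1)
            params["bn_beta"] = np.zeros(h1)
        params["W3"] = uniform((h1, h2), h1)
        if arch.bias_terms:
            params["b3"] = uniform((h2,), h1)
        if arch.use_classification:
            params["Wc"] = uniform((h2, 1), h2)
            if arch.bias_terms:
                params["bc"] = uniform((1,), h2)
        params["Wp"] = uniform((h2, 1), h2)
        if arch.bias_terms:
            params["bp"] = uniform((1,), h2)
        bn_state = {"running_mean": np.zeros(h1), "running_var": np.ones(h1)}
        return cls(arch, params, bn_state)

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def train_mode(self) -> "SurvNetModel":
        self.mode = "training"
        return self

    def eval_mode(self) -> "SurvNetModel":
        self.mode = "inference"
        return self

    def state_copy(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "bn_state": {k: v.copy() for k, v in self.bn_state.items()},
        }

    def load_state(self, state: dict) -> None:
        self.params = {k: v.copy() for k, v in state["params"].items()}
        self.bn_state = {k: v.copy() for k, v in state["bn_state"].items()}

    # -- forward ----------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        rng: Optional[np.random.Generator] = None,
        return_cache: bool = False,
    ):
        """Run the network on a batch.

        In training mode batch-norm uses (and updates) batch statistics and
        dropout draws a mask from ``rng``; a batch of one row is rejected
        because its batch variance is degenerate.
        """
        arch = self.architecture
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != arch.input_dim:
            raise ValueError(
                f"expected batch of shape (n, {arch.input_dim}), got {X.shape}"
            )
        training = self.mode == "training"
        if training and arch.use_batchnorm and X.shape[0] < 2:
            raise ValueError("batch size must be >= 2 in training mode with batch-norm")

        P = self.params
        cache: dict = {"X": X}

        z2 = X @ P["We"] + (P["be"] if "be" in P else 0.0)
        a2 = np.tanh(z2)
        cache["a2"] = a2

        x_star = None
        if arch.use_reconstruction:
            x_star = a2 @ P["Wd"] + (P["bd"] if "bd" in P else 0.0)

        if arch.use_batchnorm:
            eps = arch.batchnorm_epsilon
            if training:
                mu = a2.mean(axis=0)
                var = a2.var(axis=0)
                self.bn_state["running_mean"] = (
                    (1 - BN_MOMENTUM) * self.bn_state["running_mean"] + BN_MOMENTUM * mu
                )
                self.bn_state["running_var"] = (
                    (1 - BN_MOMENTUM) * self.bn_state["running_var"] + BN_MOMENTUM * var
                )
            else:
                mu = self.bn_state["running_mean"]
                var = self.bn_state["running_var"]
            inv_std = 1.0 / np.sqrt(var + eps)
            a2_hat = (a2 - mu) * inv_std
            a3 = P["bn_gamma"] * a2_hat + P["bn_beta"]
            cache.update(a2_hat=a2_hat, inv_std=inv_std, bn_training=training)
        else:
            a3 = a2
        cache["a3"] = a3

        z4 = a3 @ P["W3"] + (P["b3"] if "b3" in P else 0.0)
        a4 = np.tanh(z4)
        cache["a4"] = a4

        a_c = None
        if arch.use_classification:
            zc = a4 @ P["Wc"] + (P["bc"] if "bc" in P else 0.0)
            a_c = _sigmoid(zc[:, 0])
            cache["a_c"] = a_c

        if training and arch.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("dropout in training mode requires an rng")
            keep = 1.0 - arch.dropout_rate
            mask = (rng.uniform(size=a4.shape) < keep) / keep
            aL = a4 * mask
            cache["dropout_mask"] = mask
        else:
            aL = a4
        cache["aL"] = aL

        a_p = (aL @ P["Wp"] + (P["bp"] if "bp" in P else 0.0))[:, 0]
        cache["a_p"] = a_p

        if arch.use_gating:
            p_x = a_p * a_c
        else:
            p_x = a_p.copy()

        outputs = NetworkOutputs(
            x_star=x_star, a_c=a_c, a_p=a_p, p_x=p_x, a2=a2, a3=a3, a4=a4
        )
        if return_cache:
            return outputs, cache
        return outputs

    def predict_risk(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode prognosis index (mode restored afterwards)."""
        prev = self.mode
        self.eval_mode()
        try:
            return self.forward(X).p_x
        finally:
            self.mode = prev

    # -- backward ---------------------------------------------------------

    def backward(
        self,
        cache: dict,
        d_px: np.ndarray,
        d_xstar: Optional[np.ndarray] = None,
        d_ac: Optional[np.ndarray] = None,
    ) -> dict:
        """Reverse pass: upstream gradients w.r.t. the three outputs in,
        parameter gradients out.

        ``d_px``, ``d_ac`` are gradients w.r.t. the gated index and the
        survival probability itself (not its logit); ``d_xstar`` w.r.t. the
        reconstruction.  Missing terms are treated as zero.
        """
        arch = self.architecture
        P = self.params
        X, a2, a4 = cache["X"], cache["a2"], cache["a4"]
        n = X.shape[0]
        grads: dict[str, np.ndarray] = {}

        # gate: p_x = a_p * a_c
        if arch.use_gating:
            a_c, a_p = cache["a_c"], cache["a_p"]
            d_ap = d_px * a_c
            d_ac_total = d_px * a_p + (d_ac if d_ac is not None else 0.0)
        else:
            d_ap = np.asarray(d_px, dtype=float)
            d_ac_total = d_ac

        # Cox head on the (possibly dropped-out) a^L
        aL = cache["aL"]
        grads["Wp"] = aL.T @ d_ap[:, None]
        if "bp" in P:
            grads["bp"] = np.array([d_ap.sum()])
        d_aL = d_ap[:, None] @ P["Wp"].T
        if "dropout_mask" in cache:
            d_a4 = d_aL * cache["dropout_mask"]
        else:
            d_a4 = d_aL

        # classification head reads a4 directly
        if arch.use_classification and d_ac_total is not None:
            a_c = cache["a_c"]
            d_zc = d_ac_total * a_c * (1.0 - a_c)
            grads["Wc"] = a4.T @ d_zc[:, None]
            if "bc" in P:
                grads["bc"] = np.array([d_zc.sum()])
            d_a4 = d_a4 + d_zc[:, None] @ P["Wc"].T

        d_z4 = d_a4 * (1.0 - a4 ** 2)
        grads["W3"] = cache["a3"].T @ d_z4
        if "b3" in P:
            grads["b3"] = d_z4.sum(axis=0)
        d_a3 = d_z4 @ P["W3"].T

        if arch.use_batchnorm:
            a2_hat, inv_std = cache["a2_hat"], cache["inv_std"]
            grads["bn_gamma"] = (d_a3 * a2_hat).sum(axis=0)
            grads["bn_beta"] = d_a3.sum(axis=0)
            d_hat = d_a3 * P["bn_gamma"]
            if cache.get("bn_training"):
                d_a2 = (
                    inv_std
                    / n
                    * (
                        n * d_hat
                        - d_hat.sum(axis=0)
                        - a2_hat * (d_hat * a2_hat).sum(axis=0)
                    )
                )
            else:
                d_a2 = d_hat * inv_std
        else:
            d_a2 = d_a3

        if arch.use_reconstruction and d_xstar is not None:
            grads["Wd"] = a2.T @ d_xstar
            if "bd" in P:
                grads["bd"] = d_xstar.sum(axis=0)
            d_a2 = d_a2 + d_xstar @ P["Wd"].T
        elif arch.use_reconstruction:
            grads["Wd"] = np.zeros_like(P["Wd"])
            if "bd" in P:
                grads["bd"] = np.zeros_like(P["bd"])

        d_z2 = d_a2 * (1.0 - a2 ** 2)
        grads["We"] = X.T @ d_z2
        if "be" in P:
            grads["be"] = d_z2.sum(axis=0)

        for k in P:
            if k not in grads:
                grads[k] = np.zeros_like(P[k])
        return grads


def init_model(arch: ArchitectureConfig, seed: int) -> SurvNetModel:
    """Construct a model with uniform fan-in initialization."""
    return SurvNetModel.initialize(arch, seed)


def coxnet_baseline_config(arch: ArchitectureConfig) -> ArchitectureConfig:
    """The ungated, single-task baseline sharing the Cox backbone."""
    from dataclasses import replace

    return replace(
        arch, use_reconstruction=False, use_classification=False, use_gating=False
    )


# -- checkpoints (JSON, text-only) ----------------------------------------


def save_checkpoint(
    model: SurvNetModel,
    path,
    standardization_stats: Optional[StandardizationStats] = None,
    schema: Optional[CohortSchema] = None,
) -> None:
    payload = {
        "architecture": asdict(model.architecture),
        "params": {k: v.tolist() for k, v in model.params.items()},
        "bn_state": {k: v.tolist() for k, v in model.bn_state.items()},
        "standardization_stats": (
            {"location": standardization_stats.location,
             "scale": standardization_stats.scale}
            if standardization_stats is not None
            else None
        ),
        "schema": (
            [
                {"name": c.name, "kind": c.kind, "codes": c.codes}
                for c in schema.covariates
            ]
            if schema is not None
            else None
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path):
    """Restore (model, stats, schema); inference outputs are bit-identical."""
    with open(path) as fh:
        payload = json.load(fh)
    arch = ArchitectureConfig(**payload["architecture"])
    params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    bn_state = {k: np.asarray(v, dtype=float) for k, v in payload["bn_state"].items()}
    model = SurvNetModel(arch, params, bn_state)
    model.eval_mode()
    stats = None
    if payload["standardization_stats"] is not None:
        stats = StandardizationStats(
            location=payload["standardization_stats"]["location"],
            scale=payload["standardization_stats"]["scale"],
        )
    schema = None
    if payload["schema"] is not None:
        schema = CohortSchema(
            covariates=tuple(
                CovariateSpec(name=c["name"], kind=c["kind"], codes=c["codes"])
                for c in payload["schema"]
            )
        )
    return model, stats, schema
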