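"""Mini-batch optimization of the multi-task objective and model selection.

The protocol: RMSProp, 100 epochs with batch size 64, weight decay 1e-5
applied to weight matrices only, loss weights (0.2, 1, 3) with a 36-month
classification horizon, and after each epoch the validation concordance of
the inference-mode prognosis index is recorded — the parameter snapshot with
the best validation C-index is the selected model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .data_model import EncodedCohort
from .evaluation import concordance_index
from .losses import (
    LossWeights,
    NoEventsError,
    classification_loss,
    classification_loss_grad,
    classification_targets,
    cox_loss,
    cox_loss_grad,
    reconstruction_loss,
    reconstruction_loss_grad,
    total_loss,
)
from .network import WEIGHT_KEYS, ArchitectureConfig, SurvNetModel, init_model

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimizerConfig:
    """RMSProp hyperparameters, pinned to explicit numbers for reproducibility."""

    name: str = "rmsprop"
    learning_rate: float = 0.01
    smoothing: float = 0.99
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.name != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.name!r}")
        if self.learning_rate <= 0 or not (0 < self.smoothing < 1) or self.epsilon <= 0:
            raise ValueError("invalid optimizer hyperparameters")


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 64
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    weight_decay: float = 1e-5
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    n_repeats: int = 5
    normalize_cox: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch loss components and validation concordance."""

    train_loss: list[float] = field(default_factory=list)
    cox_loss: list[float] = field(default_factory=list)
    classification_loss: list[float] = field(default_factory=list)
    reconstruction_loss: list[float] = field(default_factory=list)
    val_cindex: list[float] = field(default_factory=list)
    skipped_cox_batches: int = 0

    @property
    def selected_epoch(self) -> int:
        # first epoch attaining the maximum validation C-index
        return int(np.argmax(self.val_cindex))

    @property
    def best_val_cindex(self) -> float:
        return float(np.max(self.val_cindex))


class _RMSProp:
    def __init__(self, params: dict, config: OptimizerConfig, weight_decay: float):
        self.config = config
        self.weight_decay = weight_decay
        self.v = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        c = self.config
        for k, p in params.items():
            g = grads[k]
            if self.weight_decay > 0 and k in WEIGHT_KEYS:
                g = g + self.weight_decay * p
            self.v[k] = c.smoothing * self.v[k] + (1 - c.smoothing) * g * g
            p -= c.learning_rate * g / (np.sqrt(self.v[k]) + c.epsilon)


def _batch_slices(n: int, batch_size: int) -> list[tuple[int, int]]:
    """Contiguous batch boundaries; a trailing batch of one row is folded
    into its predecessor (batch-norm needs >= 2 rows)."""
    bounds = list(range(0, n, batch_size)) + [n]
    slices = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    if len(slices) > 1 and slices[-1][1] - slices[-1][0] < 2:
        a, _ = slices[-2]
        slices[-2:] = [(a, n)]
    return slices


def train(
    model: SurvNetModel,
    train_cohort: EncodedCohort,
    val_cohort: EncodedCohort,
    config: TrainingConfig,
) -> tuple[dict, TrainingHistory]:
    """Optimize the model; return the best-validation parameter snapshot.

    Batches without any event skip the Cox term (counted and logged); an
    epoch in which no batch had events raises.  Deterministic given the
    config seed.
    """
    if train_cohort.s.sum() == 0:
        raise NoEventsError("training cohort contains no events")
    arch = model.architecture
    weights = config.loss_weights
    rng = np.random.default_rng(config.seed)
    optimizer = _RMSProp(model.params, config.optimizer, config.weight_decay)
    history = TrainingHistory()
    n = train_cohort.n

    for epoch in range(config.epochs):
        model.train_mode()
        perm = rng.permutation(n)
        epoch_losses = {"total": 0.0, "cox": 0.0, "cls": 0.0, "rec": 0.0}
        n_batches = 0
        cox_batches = 0
        for a, b in _batch_slices(n, config.batch_size):
            idx = perm[a:b]
            X = train_cohort.X[idx]
            R = train_cohort.R[idx]
            t = train_cohort.t[idx]
            s = train_cohort.s[idx]
            outputs, cache = model.forward(X, rng=rng, return_cache=True)

            l_cox = 0.0
            d_px = np.zeros_like(outputs.p_x)
            has_events = s.sum() > 0
            if has_events:
                l_cox = cox_loss(outputs.p_x, t, s, normalize=config.normalize_cox)
                d_px = weights.alpha * cox_loss_grad(
                    outputs.p_x, t, s, normalize=config.normalize_cox
                )
                cox_batches += 1
            else:
                history.skipped_cox_batches += 1

            l_cls = 0.0
            d_ac = None
            if arch.use_classification:
                tg = classification_targets(t, s, weights.horizon_T)
                l_cls = classification_loss(outputs.a_c, tg)
                d_ac = weights.beta * classification_loss_grad(outputs.a_c, tg)

            l_rec = 0.0
            d_xstar = None
            if arch.use_reconstruction:
                l_rec = reconstruction_loss(X, outputs.x_star, R)
                d_xstar = weights.gamma * reconstruction_loss_grad(
                    X, outputs.x_star, R
                )

            grads = model.backward(cache, d_px, d_xstar=d_xstar, d_ac=d_ac)
            optimizer.step(model.params, grads)

            epoch_losses["total"] += total_loss(l_cox, l_cls, l_rec, weights, arch)
            epoch_losses["cox"] += l_cox
            epoch_losses["cls"] += l_cls
            epoch_losses["rec"] += l_rec
            n_batches += 1

        if cox_batches == 0:
            raise NoEventsError(
                f"epoch {epoch}: no batch contained events; "
                "increase batch size or stratify batches"
            )

        model.eval_mode()
        val_risk = model.forward(val_cohort.X).p_x
        c = concordance_index(val_risk, val_cohort.t, val_cohort.s)
        history.train_loss.append(epoch_losses["total"] / n_batches)
        history.cox_loss.append(epoch_losses["cox"] / max(cox_batches, 1))
        history.classification_loss.append(epoch_losses["cls"] / n_batches)
        history.reconstruction_loss.append(epoch_losses["rec"] / n_batches)
        history.val_cindex.append(c)
        if history.val_cindex[-1] == history.best_val_cindex and (
            history.selected_epoch == epoch
        ):
            best_state = model.state_copy()
        logger.debug(
            "epoch %d: loss %.4f val C %.4f", epoch, history.train_loss[-1], c
        )

    if history.skipped_cox_batches:
        logger.info(
            "skipped Cox term in %d batches without events",
            history.skipped_cox_batches,
        )
    model.load_state(best_state)
    model.eval_mode()
    return best_state, history


@dataclass
class RepeatSummary:
    """Per-seed selected-model test concordances and their quartile summary."""

    seeds: list[int]
    test_cindex: list[float]

    @property
    def median(self) -> float:
        return float(np.median(self.test_cindex))

    @property
    def quartiles(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.test_cindex, 25)),
            float(np.percentile(self.test_cindex, 75)),
        )


def repeat_runs(
    arch: ArchitectureConfig,
    splits: tuple[EncodedCohort, EncodedCohort, EncodedCohort],
    config: TrainingConfig,
    k: Optional[int] = None,
) -> RepeatSummary:
    """Train ``k`` models from independent seeds; evaluate each selected
    model on the test split (the data behind a repeat-run boxplot)."""
    if k is None:
        k = config.n_repeats
    if k < 1:
        raise ValueError("k must be >= 1")
    train_cohort, val_cohort, test_cohort = splits
    seed_seq = np.random.SeedSequence(config.seed)
    seeds = [int(child.generate_state(1)[0]) for child in seed_seq.spawn(k)]
    scores = []
    for run_seed in seeds:
        model = init_model(arch, seed=run_seed)
        run_config = replace(config, seed=run_seed)
        train(model, train_cohort, val_cohort, run_config)
        risk = model.predict_risk(test_cohort.X)
        scores.append(concordance_index(risk, test_cohort.t, test_cohort.s))
    return RepeatSummary(seeds=seeds, test_cindex=scores)
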