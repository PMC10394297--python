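"""Joint minimax training of the full detector.

The total objective combines the seven loss terms

    L_sum = L_cls2 + λ·(L_cent + L_cls1 + L_subject + L_max_divergence)
                   − λ·(L_global + L_local),        λ = 0.1,

where L_subject is the patient-classifier loss of the separation stage.
The feature extractor and classifiers descend L_sum while the patient
discriminators ascend it; the ascent is realized by the gradient reversal
layer (GRL) rather than explicit alternating updates: discriminators are
trained on their plain cross-entropies, and the GRL multiplies the
gradient flowing back into the features by −λ, which reproduces exactly
the stated update directions (asserted in the test suite).  An explicit
alternating-update mode is available for stability experiments.

Protocol defaults follow the intended deployment: full-batch training
(one optimizer step per epoch — required so all training features are
available, e.g. for the class centers), Adam at lr 0.005 for all network
parameters (the auxiliary heads G_c1/G_p are trained jointly), a
dedicated lr 0.05 optimizer for the class centers, 200 epochs, no early
stopping.  A minibatch mode exists for large cohorts but deviates from
that protocol.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, TrainingDivergenceError, ValidationError
from .feature_separation import (
    SeparationNet,
    category_cls_loss_1,
    max_divergence_loss,
    patient_cls_loss,
    recombine,
    split_features,
)
from .invariant_adversarial import (
    CategoryClassifier,
    ClassCenters,
    Discriminators,
    category_cls_loss_2,
    center_loss,
    global_adversarial_loss,
    gradient_reversal,
    local_adversarial_loss,
    one_hot_categories,
)
from .io_segmentation import SegmentBatch
from .wavelet_frontend import Frontend, FrontendConfig

__all__ = [
    "VARIANTS",
    "LossBreakdown",
    "ModelConfig",
    "TrainConfig",
    "SeizureDetector",
    "TrainedModel",
    "total_loss",
    "train_model",
    "grid_search",
]

VARIANTS = ("full", "no_separation", "dann_only", "mada_only")


# ---------------------------------------------------------------------------
# Configuration and loss bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the full detector."""

    frontend: FrontendConfig = field(default_factory=FrontendConfig)
    classifier_hidden: int = 64
    disc_hidden: tuple[int, int] = (64, 32)
    # which features the discriminators see: the recombined F'_all
    # (the default wiring) or the category half only (ablation option)
    disc_features: str = "combined"


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol.

    ``grl_lambda`` defaults to ``lambda_`` (a single knob ties the GRL
    scale to the Eq-weighting); ``variant`` selects the ablation arm.
    """

    epochs: int = 200
    lr_network: float = 0.005
    lr_centers: float = 0.05
    lambda_: float = 0.1
    grl_lambda: float | None = None
    seed: int = 0
    batch_mode: str = "full"  # "full" (protocol) or "minibatch"
    batch_size: int = 256
    device: str = "cpu"
    variant: str = "full"
    mada_style_soft_labels: bool = False
    # per-sample ceiling on the squared half-distance of the max-divergence
    # loss: "auto" = 5 × half-feature dimension (the loss is unbounded below
    # and would otherwise inflate feature scale without limit under long
    # full-batch training); None disables clipping
    max_divergence_clip: float | str | None = "auto"
    adversarial_mode: str = "grl"  # or "alternating"

    def __post_init__(self):
        if self.epochs < 1 or self.lr_network <= 0 or self.lr_centers <= 0:
            raise ConfigurationError("epochs and learning rates must be positive")
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"variant must be one of {VARIANTS}")
        if self.batch_mode not in ("full", "minibatch"):
            raise ConfigurationError("batch_mode must be 'full' or 'minibatch'")

    @property
    def effective_grl_lambda(self) -> float:
        return self.lambda_ if self.grl_lambda is None else self.grl_lambda


@dataclass
class LossBreakdown:
    """Named scalar loss terms of one training step.

    Terms absent from the active variant are ``None`` and drop out of the
    combination (and of the serialized history).
    """

    l_cls_2: float
    l_cent: float
    l_cls_1: float | None = None
    l_p: float | None = None
    l_max_divergence: float | None = None
    l_global: float | None = None
    l_local: float | None = None
    lambda_: float = 0.1

    def as_dict(self) -> dict[str, float]:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = float(v)
        out["l_sum"] = total_loss(self)
        return out


def total_loss(parts: LossBreakdown) -> float:
    """Combine the named terms into L_sum (absent terms contribute zero)."""
    terms = {
        f.name: getattr(parts, f.name)
        for f in dataclasses.fields(parts)
        if f.name != "lambda_"
    }
    for name, v in terms.items():
        if v is not None and not np.isfinite(v):
            raise TrainingDivergenceError(name, epoch=-1)
    z = lambda v: 0.0 if v is None else float(v)
    lam = parts.lambda_
    return (
        z(terms["l_cls_2"])
        + lam * (z(terms["l_cent"]) + z(terms["l_cls_1"]) + z(terms["l_p"]) + z(terms["l_max_divergence"]))
        - lam * (z(terms["l_global"]) + z(terms["l_local"]))
    )


# ---------------------------------------------------------------------------
# The assembled detector
# ---------------------------------------------------------------------------


class SeizureDetector(ad.Module):
    """Front-end + separation network + invariant adversarial network."""

    def __init__(self, model_config: ModelConfig, n_patients: int, rng: np.random.Generator):
        super().__init__()
        self.model_config = model_config
        self.n_patients = n_patients
        self.frontend = Frontend(model_config.frontend, rng)
        d = self.frontend.feature_dim
        self.separation = SeparationNet(d, n_patients, rng)
        self.classifier = CategoryClassifier(d, rng, hidden=model_config.classifier_hidden)
        disc_dim = d // 2 if model_config.disc_features == "category" else d
        self.discriminators = Discriminators(disc_dim, n_patients, rng, hidden=model_config.disc_hidden)
        self.centers = ClassCenters(2, model_config.classifier_hidden)

    def extract(self, x: Tensor, use_separation: bool = True):
        """Return (f_all, separated-or-None, F'_all)."""
        f_all = self.frontend(x)
        if use_separation:
            sep = split_features(f_all)
            return f_all, sep, recombine(sep)
        return f_all, None, f_all

    def discriminator_input(self, sep, f_prime: Tensor) -> Tensor:
        if self.model_config.disc_features == "category" and sep is not None:
            return sep.category_related
        return f_prime

    def network_parameters(self) -> list[Tensor]:
        """θ_f, θ_c1, θ_p, θ_c2 — everything the network optimizer updates
        together with the discriminator parameters (single Adam; the GRL
        routes the adversarial sign)."""
        return self.parameters()


def _step_losses(
    model: SeizureDetector,
    x: Tensor,
    y: np.ndarray,
    d: np.ndarray,
    config: TrainConfig,
):
    """One forward pass: all active loss tensors + diagnostics."""
    use_sep = config.variant != "no_separation"
    f_all, sep, f_prime = model.extract(x, use_separation=use_sep)

    tensors: dict[str, Tensor] = {}
    if use_sep:
        clip = config.max_divergence_clip
        if clip == "auto":
            clip = 5.0 * sep.half_dim
        tensors["l_cls_1"] = category_cls_loss_1(model.separation, sep, y)
        tensors["l_p"] = patient_cls_loss(model.separation, sep, d)
        tensors["l_max_divergence"] = max_divergence_loss(sep, clip=clip)

    feats, logits, l_cls_2 = category_cls_loss_2(model.classifier, f_prime, y)
    tensors["l_cls_2"] = l_cls_2
    tensors["l_cent"] = center_loss(feats, y, model.centers)

    disc_in = model.discriminator_input(sep, f_prime)
    grl_in = gradient_reversal(disc_in, config.effective_grl_lambda)
    diagnostics: dict[str, float] = {}
    if config.variant in ("full", "no_separation", "dann_only"):
        tensors["l_global"] = global_adversarial_loss(model.discriminators, grl_in, d)
        g_pred = np.argmax(model.discriminators.g_g(disc_in.detach()).data, axis=1)
        diagnostics["disc_global_acc"] = float((g_pred == d).mean())
    if config.variant in ("full", "no_separation", "mada_only"):
        if config.mada_style_soft_labels:
            weights = ad.softmax(logits)
        else:
            weights = one_hot_categories(y)
        tensors["l_local"] = local_adversarial_loss(model.discriminators, grl_in, weights, d)
    return tensors, feats, logits, diagnostics


def _combine_backward(tensors: dict[str, Tensor], lam: float, n: int) -> Tensor:
    """The tensor actually backpropagated.

    Adversarial cross-entropies enter with +1 weight — descent trains the
    discriminators — while the GRL scales and negates their gradient into
    the features, realizing the −λ of the printed objective for θ_f.

    The center and max-divergence terms are batch *sums*; here they are
    normalized by the batch size so each term's per-sample gradient scale
    matches the 1/N-averaged cross-entropies.  Under full-batch training
    an unnormalized sum would make the effective weight of those terms
    grow linearly with cohort size and swamp the classification signal;
    λ = 0.1 is only meaningful between terms of comparable scale.  The
    *reported* loss values keep the summed definitions.
    """
    out = tensors["l_cls_2"] + (lam / n) * tensors["l_cent"]
    for name in ("l_cls_1", "l_p"):
        if name in tensors:
            out = out + lam * tensors[name]
    if "l_max_divergence" in tensors:
        out = out + (lam / n) * tensors["l_max_divergence"]
    for name in ("l_global", "l_local"):
        if name in tensors:
            out = out + tensors[name]
    return out


def _breakdown(tensors: dict[str, Tensor], lam: float, epoch: int) -> LossBreakdown:
    values = {}
    for name, t in tensors.items():
        v = float(t.data)
        if not np.isfinite(v):
            raise TrainingDivergenceError(name, epoch)
        values[name] = v
    return LossBreakdown(lambda_=lam, **values)


@dataclass
class TrainedModel:
    """A trained detector plus everything needed to reuse or audit it."""

    model: SeizureDetector
    model_config: ModelConfig
    train_config: TrainConfig
    patient_index: dict[int, int]  # original patient label -> contiguous index
    history: list[dict]

    # -- inference ----------------------------------------------------------
    def predict_proba(self, samples: np.ndarray) -> np.ndarray:
        """[N, 2] class probabilities (column 1 = seizure)."""
        self.model.eval()
        x = Tensor(np.asarray(samples, dtype=np.float64))
        use_sep = self.train_config.variant != "no_separation"
        _, _, f_prime = self.model.extract(x, use_separation=use_sep)
        _, logits = self.model.classifier(f_prime)
        return ad.softmax(logits)

    def predict(self, samples: np.ndarray) -> np.ndarray:
        """argmax class; exact probability ties break toward class 0."""
        probs = self.predict_proba(samples)
        return np.argmax(probs, axis=1)

    def invariant_features(self, samples: np.ndarray) -> np.ndarray:
        """G_c2's penultimate activations (the invariant feature space)."""
        self.model.eval()
        x = Tensor(np.asarray(samples, dtype=np.float64))
        use_sep = self.train_config.variant != "no_separation"
        _, _, f_prime = self.model.extract(x, use_separation=use_sep)
        return self.model.classifier.features(f_prime).data

    def separated_features(self, samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(category half, patient half) of the front-end features."""
        self.model.eval()
        x = Tensor(np.asarray(samples, dtype=np.float64))
        _, sep, _ = self.model.extract(x, use_separation=True)
        return sep.category_related.data, sep.patient_related.data

    # -- persistence --------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        state = self.model.state_dict()
        state["__centers__"] = self.model.centers.centers
        np.savez(directory / "parameters.npz", **state)
        meta = {
            "model_config": _config_to_dict(self.model_config),
            "train_config": dataclasses.asdict(self.train_config),
            "n_patients": self.model.n_patients,
            "patient_index": {str(k): v for k, v in self.patient_index.items()},
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        with open(directory / "history.jsonl", "w") as fh:
            for row in self.history:
                fh.write(json.dumps(row) + "\n")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        model_config = _config_from_dict(meta["model_config"])
        train_config = TrainConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["train_config"].items()
        })
        model = SeizureDetector(model_config, meta["n_patients"], np.random.default_rng(0))
        with np.load(directory / "parameters.npz") as data:
            state = {k: data[k] for k in data.files}
        model.centers.centers = state.pop("__centers__")
        model.load_state_dict(state)
        history = [
            json.loads(line)
            for line in (directory / "history.jsonl").read_text().splitlines()
            if line.strip()
        ]
        return cls(
            model=model,
            model_config=model_config,
            train_config=train_config,
            patient_index={int(k): v for k, v in meta["patient_index"].items()},
            history=history,
        )


def _config_to_dict(mc: ModelConfig) -> dict:
    out = dataclasses.asdict(mc)
    return out


def _config_from_dict(d: dict) -> ModelConfig:
    fe = FrontendConfig(**d["frontend"])
    rest = {k: v for k, v in d.items() if k != "frontend"}
    if "disc_hidden" in rest:
        rest["disc_hidden"] = tuple(rest["disc_hidden"])
    return ModelConfig(frontend=fe, **rest)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def _assemble(batches: Sequence[SegmentBatch]):
    x = np.concatenate([b.samples for b in batches])
    y = np.concatenate([b.category_labels for b in batches])
    d_raw = np.concatenate([b.patient_labels for b in batches])
    uniq = sorted(set(int(v) for v in d_raw))
    index = {p: i for i, p in enumerate(uniq)}
    d = np.array([index[int(v)] for v in d_raw])
    return x, y, d, index


def train_model(
    train_patients: Sequence[SegmentBatch],
    config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> TrainedModel:
    """Train the detector on labeled per-patient batches.

    Requires at least two training patients (the adversarial terms need
    patient diversity); patient labels are remapped to contiguous indices.
    Full-batch mode performs exactly one optimizer step per epoch; with a
    fixed seed the run is bit-reproducible.
    """
    if any(b.category_labels is None or b.patient_labels is None for b in train_patients):
        raise ValidationError("all training batches must be labeled")
    x_np, y, d, index = _assemble(train_patients)
    if len(index) < 2:
        raise ConfigurationError("training needs at least two patients")
    shapes = {b.samples.shape[1:] for b in train_patients}
    if len(shapes) > 1:
        raise ValidationError(f"incompatible batch shapes: {shapes}")

    if model_config is None:
        model_config = ModelConfig(
            frontend=FrontendConfig(n_channels=x_np.shape[1], window_len=x_np.shape[2])
        )
    if model_config.frontend.n_channels != x_np.shape[1]:
        raise ConfigurationError("model channel count does not match the data")

    ss = np.random.SeedSequence(config.seed)
    init_seq, shuffle_seq = ss.spawn(2)
    model = SeizureDetector(model_config, len(index), np.random.default_rng(init_seq))
    opt = ad.Adam(model.parameters(), lr=config.lr_network)
    shuffle_rng = np.random.default_rng(shuffle_seq)

    history: list[dict] = []
    model.train(True)
    for epoch in range(config.epochs):
        if config.batch_mode == "full":
            slices = [np.arange(len(y))]
        else:
            order = shuffle_rng.permutation(len(y))
            slices = [
                order[i : i + config.batch_size]
                for i in range(0, len(order), config.batch_size)
            ]
        epoch_rows = []
        for idx in slices:
            tensors, feats, _, diagnostics = _step_losses(
                model, Tensor(x_np[idx]), y[idx], d[idx], config
            )
            parts = _breakdown(tensors, config.lambda_, epoch)
            backward = _combine_backward(tensors, config.lambda_, len(idx))
            opt.zero_grad()
            backward.backward()
            opt.step()
            model.centers.update(feats.data, y[idx], config.lr_centers)
            row = parts.as_dict()
            row.update(diagnostics)
            epoch_rows.append(row)
        if len(epoch_rows) == 1:
            record = epoch_rows[0]
        else:
            keys = set().union(*epoch_rows)
            record = {k: float(np.mean([r[k] for r in epoch_rows if k in r])) for k in keys}
        record["epoch"] = epoch
        history.append(record)
    model.eval()
    return TrainedModel(
        model=model,
        model_config=model_config,
        train_config=config,
        patient_index=index,
        history=history,
    )


# ---------------------------------------------------------------------------
# Hyperparameter grid search
# ---------------------------------------------------------------------------


def grid_search(
    cohort: Sequence[SegmentBatch],
    grid: dict[str, list],
    base_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
) -> tuple[TrainConfig, "pd.DataFrame"]:
    """Exhaustive search scored by inner leave-one-patient-out accuracy.

    Ties resolve toward the smallest λ, then the smallest network lr.
    Returns the winning config and the full score table.
    """
    import itertools

    import pandas as pd

    from .evaluation import loso_cross_validation

    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValidationError("grid must be non-empty")
    base = base_config or TrainConfig()
    names = sorted(grid)
    rows = []
    candidates = []
    for combo in itertools.product(*(grid[n] for n in names)):
        cfg = dataclasses.replace(base, **dict(zip(names, combo)))
        try:
            report = loso_cross_validation(cohort, cfg, model_config)
            score = report.summary["acc_mean"]
        except TrainingDivergenceError:
            score = 0.0  # a diverging configuration ranks last
        rows.append({**dict(zip(names, combo)), "mean_acc": score})
        candidates.append((score, -cfg.lambda_, -cfg.lr_network, cfg))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]), reverse=True)
    return candidates[0][3], pd.DataFrame(rows)
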