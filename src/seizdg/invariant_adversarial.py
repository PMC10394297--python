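"""Invariant feature extraction network.

Patient-invariant features are induced adversarially: patient
discriminators try to recover the patient identity from the features while
the feature extractor — coupled through a gradient reversal layer (GRL) —
is updated to defeat them.

* The **global** discriminator G_g sees every sample and aligns the
  marginal feature distribution across patients (DANN-style).
* Two **local** discriminators G_l1/G_l2, one per category, see features
  masked by the true one-hot class indicator y_ik (non-members contribute
  zero vectors, keeping the 1/N normalization and static batch shapes) and
  align the per-class conditional distributions (MADA-style, but with true
  labels rather than predicted soft labels; the soft-label variant is
  retained as an option for ablations).
* A **center loss** ½ Σ‖x_i − c_{y_i}‖² (a sum, not a mean) compacts each
  class around a learnable center; centers are updated only by their
  dedicated optimizer rule, while feature gradients flow normally.
* The main category classifier G_c2 predicts seizure/normal; its
  penultimate activations are the features used by the center loss and by
  downstream feature exports.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, gradient_reversal
from .errors import StateError, ValidationError

__all__ = [
    "gradient_reversal",
    "one_hot_categories",
    "Discriminators",
    "CategoryClassifier",
    "ClassCenters",
    "global_adversarial_loss",
    "local_adversarial_loss",
    "center_loss",
    "category_cls_loss_2",
]


def one_hot_categories(y: np.ndarray, n_categories: int = 2) -> np.ndarray:
    """One-hot encode true class labels; rows sum to exactly one."""
    y = np.asarray(y)
    if y.min() < 0 or y.max() >= n_categories:
        raise ValidationError("label outside category range")
    out = np.zeros((y.shape[0], n_categories))
    out[np.arange(y.shape[0]), y] = 1.0
    return out


class Discriminators(ad.Module):
    """Global + two per-class local patient discriminators.

    Each is a two-hidden-layer MLP (widths 64, 32 by default, ELU) with
    ``n_patients`` softmax outputs, operating on features passed through
    gradient reversal.
    """

    def __init__(
        self,
        feature_dim: int,
        n_patients: int,
        rng: np.random.Generator,
        hidden: tuple[int, int] = (64, 32),
    ):
        super().__init__()
        self.n_patients = n_patients
        widths = [feature_dim, *hidden, n_patients]
        self.g_g = ad.MLP(widths, rng)
        self.g_l1 = ad.MLP(widths, rng)
        self.g_l2 = ad.MLP(widths, rng)

    def locals(self) -> tuple[ad.MLP, ad.MLP]:
        return self.g_l1, self.g_l2


class CategoryClassifier(ad.Module):
    """G_c2: hidden ELU layer (the invariant feature space) + linear head."""

    def __init__(self, feature_dim: int, rng: np.random.Generator, hidden: int = 64):
        super().__init__()
        self.hidden_dim = hidden
        self.body = ad.Linear(feature_dim, hidden, rng)
        self.head = ad.Linear(hidden, 2, rng)

    def features(self, f: Tensor) -> Tensor:
        """Penultimate activations — the input space of the center loss."""
        return ad.elu(self.body(f))

    def __call__(self, f: Tensor) -> tuple[Tensor, Tensor]:
        feats = self.features(f)
        return feats, self.head(feats)


class ClassCenters:
    """Learnable per-category centers, updated only by their own optimizer.

    The update follows the canonical center-loss rule: the per-class
    gradient Σ(c_y − x_i) is normalized by (1 + n_y) before the lr-scaled
    step, which keeps the full-batch update contractive.
    """

    def __init__(self, n_categories: int, dim: int):
        self.centers = np.zeros((n_categories, dim))
        self.initialized = True

    def update(self, features: np.ndarray, y: np.ndarray, lr: float) -> None:
        for k in range(self.centers.shape[0]):
            members = features[y == k]
            if members.size == 0:
                continue
            delta = (self.centers[k] - members).sum(axis=0) / (1.0 + len(members))
            self.centers[k] -= lr * delta


def global_adversarial_loss(disc: Discriminators, features: Tensor, d: np.ndarray) -> Tensor:
    """Mean cross-entropy of the global discriminator vs patient labels."""
    d = np.asarray(d)
    if d.min() < 0 or d.max() >= disc.n_patients:
        raise ValidationError("patient label outside [0, n_patients)")
    return ad.softmax_cross_entropy(disc.g_g(features), d, reduction="mean")


def local_adversarial_loss(
    disc: Discriminators,
    features: Tensor,
    y_weights: np.ndarray,
    d: np.ndarray,
    normalized: bool = True,
) -> Tensor:
    """Per-class conditional adversarial loss.

    ``y_weights`` is [N, 2]: the true one-hot indicators (rows summing to
    one), or predicted class probabilities in the soft ("MADA-style")
    variant.  For class k the features are scaled per sample by
    ``y_weights[:, k]`` and fed to G_l^k; the two summed cross-entropies
    are averaged by 1/N.  ``normalized=False`` skips the row-sum check
    (diagnostics only, e.g. probing the all-ones degeneracy).
    """
    d = np.asarray(d)
    y_weights = np.asarray(y_weights)
    if y_weights.shape != (features.shape[0], 2):
        raise ValidationError("y_weights must be [N, 2]")
    if normalized and not np.allclose(y_weights.sum(axis=1), 1.0):
        raise ValidationError("per-sample class weights must sum to one")
    if d.min() < 0 or d.max() >= disc.n_patients:
        raise ValidationError("patient label outside [0, n_patients)")
    n = features.shape[0]
    total = None
    for k, g_l in enumerate(disc.locals()):
        masked = features * Tensor(y_weights[:, k : k + 1])
        ce = ad.softmax_cross_entropy(g_l(masked), d, reduction="sum")
        total = ce if total is None else total + ce
    return total * (1.0 / n)


def center_loss(features: Tensor, y: np.ndarray, centers: ClassCenters) -> Tensor:
    """½ Σ_i ‖x_i − c_{y_i}‖² over the batch (a sum — no 1/M)."""
    if not getattr(centers, "initialized", False):
        raise StateError("class centers are not initialized")
    y = np.asarray(y)
    target = Tensor(centers.centers[y])
    diff = features - target
    return 0.5 * (diff * diff).sum()


def category_cls_loss_2(classifier: CategoryClassifier, f: Tensor, y: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
    """Main classification loss; returns (features, logits, mean cross-entropy)."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValidationError("empty batch")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("category labels must be in {0, 1}")
    feats, logits = classifier(f)
    return feats, logits, ad.softmax_cross_entropy(logits, y, reduction="mean")


def predict_classes(logits: Tensor | np.ndarray) -> np.ndarray:
    """argmax of the softmax; exact ties break toward class 0."""
    probs = ad.softmax(logits)
    return np.argmax(probs, axis=1)
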