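"""Feature separation (disentanglement) network.

The front-end feature vector is split exactly in half by index: the first
half is declared the category-related component, the second half the
patient-related component.  Three losses enforce the declaration:

* a category classifier G_c1 on the first half (cross-entropy vs the
  seizure/normal label);
* a patient classifier G_p on the second half (cross-entropy vs the
  patient index);
* a max-divergence loss, the negated summed squared distance between the
  halves, whose minimization pushes them apart (it is ≤ 0, with equality
  iff the halves coincide; unbounded below, damped only by the small
  λ weight in the joint objective — an optional per-sample clip ceiling
  is available for monitoring runaway separation).

The halves are then re-concatenated (category first) into F'_all, which
feeds the invariant-feature network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SeparatedFeatures",
    "SeparationNet",
    "split_features",
    "recombine",
    "category_cls_loss_1",
    "patient_cls_loss",
    "max_divergence_loss",
]


@dataclass
class SeparatedFeatures:
    """The two half-features and their dimension."""

    category_related: Tensor
    patient_related: Tensor

    @property
    def half_dim(self) -> int:
        return self.category_related.shape[1]


def split_features(f_all: Tensor) -> SeparatedFeatures:
    """Exact half split by index (category half first)."""
    f_all = ad.as_tensor(f_all)
    d = f_all.shape[1]
    if d % 2 != 0:
        raise ConfigurationError(f"feature dimension {d} is odd; the half split needs even")
    half = d // 2
    return SeparatedFeatures(
        category_related=f_all[:, :half],
        patient_related=f_all[:, half:],
    )


def recombine(sep: SeparatedFeatures) -> Tensor:
    """F'_all = [category_related | patient_related]."""
    return ad.concat([sep.category_related, sep.patient_related], axis=1)


def max_divergence_loss(sep: SeparatedFeatures, clip: float | None = None) -> Tensor:
    """Negated squared Euclidean distance between the halves, summed over the batch.

    ``clip`` optionally ceilings the per-sample squared distance (the loss
    is unbounded below; by default unclipped, matching the damping-by-λ
    regime of the joint objective).
    """
    if sep.category_related.shape != sep.patient_related.shape:
        raise ValidationError("feature halves must have equal dimension")
    diff = sep.category_related - sep.patient_related
    per_sample = (diff * diff).sum(axis=1)
    if clip is not None:
        # soft ceiling: min(d², clip) implemented by masking above the ceiling
        mask = (per_sample.data <= clip).astype(float)
        per_sample = per_sample * Tensor(mask) + Tensor((1.0 - mask) * clip)
    return -per_sample.sum()


class SeparationNet(ad.Module):
    """Auxiliary classifiers of the separation stage.

    G_c1 and G_p are single-hidden-layer MLPs (hidden width = half-feature
    dimension, ELU) — the smallest nontrivial probes.
    """

    def __init__(self, feature_dim: int, n_patients: int, rng: np.random.Generator):
        super().__init__()
        if feature_dim % 2 != 0:
            raise ConfigurationError("feature dimension must be even")
        half = feature_dim // 2
        self.n_patients = n_patients
        self.g_c1 = ad.MLP([half, half, 2], rng)
        self.g_p = ad.MLP([half, half, n_patients], rng)


def category_cls_loss_1(net: SeparationNet, sep: SeparatedFeatures, y: np.ndarray) -> Tensor:
    """Mean cross-entropy of G_c1(F_category_related) against the class labels."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValidationError("empty batch")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("category labels must be in {0, 1}")
    return ad.softmax_cross_entropy(net.g_c1(sep.category_related), y, reduction="mean")


def patient_cls_loss(net: SeparationNet, sep: SeparatedFeatures, d: np.ndarray) -> Tensor:
    """Mean cross-entropy of G_p(F_patient_related) against the patient labels."""
    d = np.asarray(d)
    if d.size == 0:
        raise ValidationError("empty batch")
    if d.min() < 0 or d.max() >= net.n_patients:
        raise ValidationError("patient label outside [0, n_patients)")
    return ad.softmax_cross_entropy(net.g_p(sep.patient_related), d, reduction="mean")
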