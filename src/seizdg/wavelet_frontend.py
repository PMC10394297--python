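"""Multi-level temporal-spectral feature extraction network.

The front-end turns a batch of normalized 1-s EEG windows [N, C, T] into a
flat feature vector per window by combining:

* an **embedding block** — a temporal convolution + batch normalization
  whose output is channel-concatenated with the raw input, supplying
  adaptive sub-band responses alongside the original data;
* a **spectral branch** — a five-level discrete wavelet transform with
  fixed Daubechies-4 filters implemented as a strided convolution with
  circular head/tail padding, whose detail levels are grouped into the
  physiological bands δ, θ, α, β, γ and linearly projected to a common
  width W per band;
* a **temporal branch** — five independent conv → BN → ELU stacks with
  kernel lengths {32, 32, 16, 8, 4} applied per channel (different
  receptive fields), pooled and projected to the same width W;
* a **squeeze-and-excitation step** — the five paired [spectral|temporal]
  groups are gated by sigmoid weights computed from globally pooled group
  statistics through a bottleneck, then flattened.

Band mapping at 250 Hz: five decomposition levels give dyadic sub-bands
D2 ≈ 31–62 Hz, D3 ≈ 16–31, D4 ≈ 8–16, D5 ≈ 4–8 and A5 ≈ 0–4 — the
conventional γ/β/α/θ/δ edges almost exactly — so the bands are mapped
γ=[D1|D2] (D1 keeps the supra-γ 62–125 Hz content with the fastest band),
β=D3, α=D4, θ=D5, δ=A5.  The DWT matches a
reference pyramidal transform with periodization padding exactly: the
head/tail fill is a circular extension, so the strided correlation equals
the orthonormal circular DWT, and odd-length approximations are extended
by one repeated trailing sample per level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, ValidationError

__all__ = [
    "WaveletFilters",
    "SubbandFeatures",
    "TemporalFeatures",
    "daubechies4_filters",
    "pad_head_tail",
    "conv_dwt_level",
    "wavelet_decompose",
    "spectral_branch",
    "band_coefficient_lengths",
    "FrontendConfig",
    "EmbeddingBlock",
    "SpectralHead",
    "TemporalBranch",
    "SqueezeExcite",
    "Frontend",
]

BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")

# Daubechies order-4 decomposition low-pass filter (standard 8-tap
# orthonormal coefficients; high-pass follows by quadrature mirror).
_DB4_DEC_LO = np.array(
    [
        -0.010597401784997278,
        0.032883011666982945,
        0.030841381835986965,
        -0.18703481171888114,
        -0.02798376941698385,
        0.6308807679295904,
        0.7148465705525415,
        0.23037781330885523,
    ]
)


@dataclass(frozen=True)
class WaveletFilters:
    """A scaling/wavelet decomposition filter pair with stride."""

    g: np.ndarray  # low-pass (scaling)
    h: np.ndarray  # high-pass (wavelet), quadrature mirror of g
    stride: int = 2

    @property
    def length(self) -> int:
        return len(self.g)


def daubechies4_filters() -> WaveletFilters:
    """The standard 8-tap Db4 decomposition pair.

    Satisfies Σg = √2, Σh = 0, unit energy and double-shift orthogonality.
    """
    g = _DB4_DEC_LO.copy()
    h = g[::-1].copy()
    h[0::2] *= -1.0  # quadrature mirror: h[n] = (-1)^(n+1) g[R-1-n]
    return WaveletFilters(g=g, h=h)


def pad_head_tail(x, filter_length: int):
    """Circular head/tail fill before the strided wavelet convolution.

    For filter length R the last R/2-1 samples are prepended and the first
    R/2-1 appended, giving length N + R - 2.  Accepts a plain array or a
    graph :class:`~seizdg.autodiff.Tensor` (last axis is time).
    """
    r = filter_length
    if r % 2 != 0:
        raise ValidationError("filter length must be even")
    is_tensor = isinstance(x, Tensor)
    n = x.shape[-1]
    if n < r // 2:
        raise ValidationError(f"signal length {n} too short for filter length {r}")
    half = r // 2
    if half <= 1:
        return x
    left = x[..., n - half + 1 :]
    right = x[..., : half - 1]
    if is_tensor:
        return ad.concat([left, x, right], axis=-1)
    return np.concatenate([left, x, right], axis=-1)


def conv_dwt_level(x_padded, filters: WaveletFilters):
    """One decomposition level on an already padded signal.

    Computes the strided correlations y_A(i) = Σ_r x_p(s·i + R-1-r)·g(r)
    and likewise y_D with h, i.e. the written-out convolution with the
    index origin shifted so the first full window sits at i = 0.  Output
    length is ⌊(len(x_p) − R)/s⌋ + 1.  Works on arrays of shape [..., T]
    or graph tensors.
    """
    r, s = filters.length, filters.stride
    n = x_padded.shape[-1]
    if n < r:
        raise ValidationError("padded signal shorter than filter")
    if isinstance(x_padded, Tensor):
        lead = x_padded.shape[:-1]
        flat = ad.reshape(x_padded, (-1, 1, n))
        w_a = Tensor(filters.g[::-1].reshape(1, 1, r))
        w_d = Tensor(filters.h[::-1].reshape(1, 1, r))
        y_a = ad.conv1d(flat, w_a, stride=s)
        y_d = ad.conv1d(flat, w_d, stride=s)
        length = y_a.shape[-1]
        return (
            ad.reshape(y_a, lead + (length,)),
            ad.reshape(y_d, lead + (length,)),
        )
    from numpy.lib.stride_tricks import sliding_window_view

    cols = sliding_window_view(np.asarray(x_padded), r, axis=-1)[..., ::s, :]
    y_a = cols @ filters.g[::-1]
    y_d = cols @ filters.h[::-1]
    return y_a, y_d


def _extend_odd(x):
    """Repeat the trailing sample when the time axis has odd length."""
    if x.shape[-1] % 2 == 0:
        return x
    last = x[..., -1:]
    if isinstance(x, Tensor):
        return ad.concat([x, last], axis=-1)
    return np.concatenate([x, last], axis=-1)


def wavelet_decompose(x, filters: WaveletFilters | None = None, levels: int = 5, pad_per_level: bool = True):
    """Multi-level pyramid on the approximation path.

    Returns ``(details, approx)`` where ``details = [D1, ..., D_levels]``.
    Padding is reapplied per level by default (required for the stride
    arithmetic to stay valid on the shrinking approximation).
    """
    filters = filters or daubechies4_filters()
    details = []
    a = x
    for lev in range(levels):
        a = _extend_odd(a)
        if pad_per_level or lev == 0:
            ap = pad_head_tail(a, filters.length)
        else:
            ap = a
        a, d = conv_dwt_level(ap, filters)
        details.append(d)
    return details, a


@dataclass
class SubbandFeatures:
    """Wavelet coefficients grouped into the five physiological bands."""

    f_delta: object
    f_theta: object
    f_alpha: object
    f_beta: object
    f_gamma: object

    def in_band_order(self):
        return (self.f_delta, self.f_theta, self.f_alpha, self.f_beta, self.f_gamma)


@dataclass
class TemporalFeatures:
    """Outputs of the five temporal conv stacks (kernel 32, 32, 16, 8, 4)."""

    f_t1: object
    f_t2: object
    f_t3: object
    f_t4: object
    f_t5: object

    def members(self):
        return (self.f_t1, self.f_t2, self.f_t3, self.f_t4, self.f_t5)


def spectral_branch(x, levels: int = 5, filters: WaveletFilters | None = None) -> SubbandFeatures:
    """Per-channel multi-level DWT mapped onto the named bands.

    ``x`` is [..., T] (typically [N, C, T]); each band holds the raw
    coefficients.  At 250 Hz: δ=A5, θ=D5, α=D4, β=D3, γ=[D1|D2].
    """
    if x.shape[-1] < 2**levels:
        raise ValidationError("input too short for the requested decomposition depth")
    details, approx = wavelet_decompose(x, filters, levels)
    if isinstance(x, Tensor):
        gamma = ad.concat([details[0], details[1]], axis=-1)
    else:
        gamma = np.concatenate([details[0], details[1]], axis=-1)
    return SubbandFeatures(
        f_delta=approx,
        f_theta=details[4],
        f_alpha=details[3],
        f_beta=details[2],
        f_gamma=gamma,
    )


def band_coefficient_lengths(window_len: int, levels: int = 5) -> list[int]:
    """Coefficient count per band [δ, θ, α, β, γ] for a given window length."""
    lengths = []
    n = window_len
    for _ in range(levels):
        n = (n + 1) // 2  # ceil halving (odd lengths are extended)
        lengths.append(n)
    # lengths[i] is len(D_{i+1}); A_levels has the same length as D_levels
    per_band = [lengths[4], lengths[4], lengths[3], lengths[2], lengths[0] + lengths[1]]
    return per_band


# ---------------------------------------------------------------------------
# Learnable blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrontendConfig:
    """Architecture hyperparameters of the front-end.

    ``feature_width`` (W) is the common per-band width the spectral and
    temporal features are projected to; the final feature dimension is
    5 pairs × 2W = 10·W, always even as the downstream half-split requires.
    """

    n_channels: int = 22
    window_len: int = 250
    embedding_width: int = 8
    embedding_kernel: int = 15
    k: int = 32  # largest temporal kernel; heights are {k, k, k/2, k/4, k/8}
    feature_width: int = 32
    temporal_filters: int = 8
    temporal_pool: int = 4
    se_ratio: int = 4
    levels: int = 5
    pad_per_level: bool = True

    @property
    def kernel_heights(self) -> tuple[int, ...]:
        k = self.k
        return (k, k, k // 2, k // 4, k // 8)

    @property
    def feature_dim(self) -> int:
        return 10 * self.feature_width


class EmbeddingBlock(ad.Module):
    """Temporal convolution + BN, channel-concatenated with the raw input."""

    def __init__(self, config: FrontendConfig, rng: np.random.Generator):
        super().__init__()
        if config.embedding_kernel % 2 == 0:
            raise ConfigurationError("embedding kernel must be odd (same-length output)")
        self.config = config
        self.conv = ad.Conv1d(config.n_channels, config.embedding_width, config.embedding_kernel, rng)
        self.bn = ad.BatchNorm(config.embedding_width)

    def __call__(self, x: Tensor) -> Tensor:
        half = self.config.embedding_kernel // 2
        zeros = Tensor(np.zeros((x.shape[0], x.shape[1], half)))
        padded = ad.concat([zeros, x, zeros], axis=2)
        emb = self.bn(self.conv(padded))
        return ad.concat([x, emb], axis=1)


class SpectralHead(ad.Module):
    """Fixed DWT followed by a learnable per-band projection to width W."""

    def __init__(self, config: FrontendConfig, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.filters = daubechies4_filters()
        self.band_lengths = band_coefficient_lengths(config.window_len, config.levels)
        for band, length in zip(BAND_ORDER, self.band_lengths):
            setattr(
                self,
                f"proj_{band}",
                ad.Linear(in_channels * length, config.feature_width, rng),
            )

    def __call__(self, x: Tensor) -> list[Tensor]:
        bands = spectral_branch(x, self.config.levels, self.filters)
        out = []
        for band, coeffs in zip(BAND_ORDER, bands.in_band_order()):
            # project per-band coefficient energies: oscillatory class
            # structure lives in sub-band power, and energies are invariant
            # to the window phase of the underlying rhythm
            energy = coeffs * coeffs
            flat = ad.reshape(energy, (energy.shape[0], -1))
            out.append(getattr(self, f"proj_{band}")(flat))
        return out


class TemporalBranch(ad.Module):
    """Five independent per-channel conv → BN → ELU stacks.

    Kernels run along time with the channel axis folded into the batch
    (each EEG channel is filtered independently); outputs are average
    pooled and projected to width W.
    """

    def __init__(self, config: FrontendConfig, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.in_channels = in_channels
        if config.window_len < config.k:
            raise ValidationError("window shorter than the largest temporal kernel")
        for i, ks in enumerate(config.kernel_heights):
            stride = max(2, ks // 4)
            setattr(self, f"conv{i}", ad.Conv1d(1, config.temporal_filters, ks, rng, stride=stride))
            setattr(self, f"bn{i}", ad.BatchNorm(config.temporal_filters))
            setattr(
                self,
                f"proj{i}",
                ad.Linear(
                    in_channels * config.temporal_filters * config.temporal_pool,
                    config.feature_width,
                    rng,
                ),
            )

    def __call__(self, x: Tensor) -> TemporalFeatures:
        n, c, t = x.shape
        flat = ad.reshape(x, (n * c, 1, t))
        feats = []
        for i in range(5):
            h = getattr(self, f"conv{i}")(flat)
            h = getattr(self, f"bn{i}")(h)
            h = ad.elu(h)
            h = ad.adaptive_avg_pool1d(h, self.config.temporal_pool)
            h = ad.reshape(h, (n, -1))
            feats.append(getattr(self, f"proj{i}")(h))
        return TemporalFeatures(*feats)


class SqueezeExcite(ad.Module):
    """Per-group sigmoid gating from globally pooled group statistics."""

    def __init__(self, n_groups: int, ratio: int, rng: np.random.Generator):
        super().__init__()
        bottleneck = max(1, n_groups // ratio)
        self.squeeze = ad.Linear(n_groups, bottleneck, rng)
        self.excite = ad.Linear(bottleneck, n_groups, rng)

    def __call__(self, groups: Tensor) -> Tensor:
        # groups: [N, n_groups, group_dim]
        z = ad.tmean(groups, axis=2)
        gates = ad.sigmoid(self.excite(ad.elu(self.squeeze(z))))
        return groups * ad.reshape(gates, (groups.shape[0], groups.shape[1], 1))


def combine_and_excite(spec: SubbandFeatures, temp: TemporalFeatures, se: SqueezeExcite) -> Tensor:
    """Pair spectral and temporal features, gate the pairs, and flatten.

    f_all = {[f_δ|f_t1], [f_θ|f_t2], [f_α|f_t3], [f_β|f_t4], [f_γ|f_t5]},
    each pair rescaled by its learned SE gate.  The flattened dimension is
    the sum of the paired group dimensions and must be even.
    """
    pairs = []
    for s, t in zip(spec.in_band_order(), temp.members()):
        if s.shape[0] != t.shape[0]:
            raise ValidationError("spectral/temporal batch mismatch")
        pairs.append(ad.concat([s, t], axis=1))
    group_dim = pairs[0].shape[1]
    stacked = ad.concat(
        [ad.reshape(p, (p.shape[0], 1, group_dim)) for p in pairs], axis=1
    )
    gated = se(stacked)
    flat = ad.reshape(gated, (gated.shape[0], -1))
    if flat.shape[1] % 2 != 0:
        raise ConfigurationError("front-end feature dimension must be even")
    return flat


class Frontend(ad.Module):
    """The full feature extraction network G_f: [N, C, T] → [N, 10·W]."""

    def __init__(self, config: FrontendConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        in_channels = config.n_channels + config.embedding_width
        self.embedding = EmbeddingBlock(config, rng)
        self.spectral = SpectralHead(config, in_channels, rng)
        self.temporal = TemporalBranch(config, in_channels, rng)
        self.se = SqueezeExcite(5, config.se_ratio, rng)

    @property
    def feature_dim(self) -> int:
        return self.config.feature_dim

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[1] != self.config.n_channels or x.shape[2] != self.config.window_len:
            raise ValidationError(
                f"expected input [N, {self.config.n_channels}, {self.config.window_len}]"
            )
        embedded = self.embedding(x)
        spec = SubbandFeatures(*self.spectral(embedded))
        temp = self.temporal(embedded)
        return combine_and_excite(spec, temp, self.se)
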