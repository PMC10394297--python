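"""The wavelet/convolution front-end: filters, padding, DWT and blocks."""

import numpy as np
import pytest
import pywt

from seizdg import autodiff as ad
from seizdg import (
    ConfigurationError,
    FrontendConfig,
    Frontend,
    ValidationError,
    conv_dwt_level,
    daubechies4_filters,
    pad_head_tail,
    spectral_branch,
    wavelet_decompose,
)
from seizdg.wavelet_frontend import (
    EmbeddingBlock,
    SqueezeExcite,
    SubbandFeatures,
    TemporalBranch,
    band_coefficient_lengths,
    combine_and_excite,
)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def test_db4_filter_identities():
    f = daubechies4_filters()
    assert f.length == 8 and len(f.h) == 8
    assert abs(f.g.sum() - np.sqrt(2)) < 1e-10
    assert abs(f.h.sum()) < 1e-10
    assert abs((f.g**2).sum() - 1) < 1e-10
    assert abs((f.h**2).sum() - 1) < 1e-10
    # double-shift orthogonality
    assert abs(np.dot(f.g[:-2], f.g[2:])) < 1e-10


def test_db4_matches_reference_library():
    f = daubechies4_filters()
    w = pywt.Wavelet("db4")
    assert np.allclose(f.g, w.dec_lo, atol=1e-12)
    assert np.allclose(f.h, w.dec_hi, atol=1e-12)


# ---------------------------------------------------------------------------
# Padding
# ---------------------------------------------------------------------------


def test_pad_head_tail_printed_example():
    x = np.arange(8.0)
    assert pad_head_tail(x, 4).tolist() == [7, 0, 1, 2, 3, 4, 5, 6, 7, 0]


def test_pad_head_tail_r8_blocks(rng):
    x = rng.normal(size=20)
    xp = pad_head_tail(x, 8)
    assert len(xp) == 20 + 8 - 2
    assert np.array_equal(xp[:3], x[-3:])
    assert np.array_equal(xp[-3:], x[:3])


def test_pad_head_tail_r2_is_identity(rng):
    x = rng.normal(size=16)
    assert np.array_equal(pad_head_tail(x, 2), x)


def test_pad_head_tail_rejects_odd_or_short():
    with pytest.raises(ValidationError):
        pad_head_tail(np.zeros(16), 5)
    with pytest.raises(ValidationError):
        pad_head_tail(np.zeros(2), 8)


# ---------------------------------------------------------------------------
# Single-level and pyramid DWT
# ---------------------------------------------------------------------------


def test_constant_signal_splits_into_scaled_mean_and_zero_detail():
    f = daubechies4_filters()
    c = 3.7
    ya, yd = conv_dwt_level(pad_head_tail(np.full(64, c), 8), f)
    assert np.allclose(yd, 0.0, atol=1e-10)
    assert np.allclose(ya, c * np.sqrt(2), atol=1e-10)


def test_high_frequency_energy_lands_in_detail():
    f = daubechies4_filters()
    t = np.arange(256)
    x = np.sin(2 * np.pi * 0.45 * t)  # 0.9 × Nyquist
    ya, yd = conv_dwt_level(pad_head_tail(x, 8), f)
    assert (yd**2).sum() / (ya**2).sum() > 10


def test_energy_conservation_per_level(rng):
    f = daubechies4_filters()
    for _ in range(10):
        x = rng.normal(size=128)
        ya, yd = conv_dwt_level(pad_head_tail(x, 8), f)
        assert np.isclose((ya**2).sum() + (yd**2).sum(), (x**2).sum(), atol=1e-9)


def test_pyramid_matches_reference_wavedec(rng):
    for _ in range(10):
        x = rng.normal(size=250)
        details, approx = wavelet_decompose(x)
        ref = pywt.wavedec(x, "db4", mode="periodization", level=5)
        ref = ref[:0:-1] + [ref[0]]  # [D1..D5, A5]
        for ours, theirs in zip(details + [approx], ref):
            assert ours.shape == theirs.shape
            assert np.allclose(ours, theirs, atol=1e-10)


# ---------------------------------------------------------------------------
# Spectral branch
# ---------------------------------------------------------------------------


def test_spectral_branch_band_structure(rng):
    x = rng.normal(size=(2, 250))
    bands = spectral_branch(x)
    lengths = [b.shape[-1] for b in bands.in_band_order()]
    assert lengths == band_coefficient_lengths(250)
    # total coefficient count ≈ input length (boundary slack from odd levels)
    assert abs(sum(lengths) - 250) <= 10


def test_six_hz_sine_peaks_in_theta():
    t = np.arange(250) / 250.0
    x = np.sin(2 * np.pi * 6.0 * t)[None, :]
    bands = spectral_branch(x)
    ms = {
        name: float(np.mean(np.asarray(b) ** 2))
        for name, b in zip(
            ("delta", "theta", "alpha", "beta", "gamma"), bands.in_band_order()
        )
    }
    assert max(ms, key=ms.get) == "theta"


def test_zero_input_gives_zero_coefficients():
    bands = spectral_branch(np.zeros((1, 250)))
    assert all(np.allclose(b, 0) for b in bands.in_band_order())


def test_spectral_branch_rejects_short_input():
    with pytest.raises(ValidationError):
        spectral_branch(np.zeros((1, 16)), levels=5)


# ---------------------------------------------------------------------------
# Learnable blocks
# ---------------------------------------------------------------------------


def _cfg(**kw):
    base = dict(n_channels=3, window_len=250, embedding_width=2,
                feature_width=8, temporal_filters=4)
    base.update(kw)
    return FrontendConfig(**base)


def test_embedding_block_concatenates_channels(rng):
    cfg = _cfg()
    block = EmbeddingBlock(cfg, rng)
    x = ad.Tensor(rng.uniform(size=(4, 3, 250)))
    out = block(x)
    assert out.shape == (4, 3 + 2, 250)  # C + E channels, time preserved
    assert np.array_equal(out.data[:, :3], x.data)  # original data first


def test_embedding_block_zero_input_zero_output(rng):
    block = EmbeddingBlock(_cfg(), rng)
    block.eval()
    out = block(ad.Tensor(np.zeros((2, 3, 250))))
    assert np.allclose(out.data[:, 3:], 0.0)  # conv bias 0, BN shift 0


def test_temporal_branch_structure(rng):
    cfg = _cfg()
    branch = TemporalBranch(cfg, in_channels=5, rng=rng)
    x = ad.Tensor(rng.uniform(size=(3, 5, 250)))
    feats = branch(x).members()
    assert len(feats) == 5
    assert all(f.shape == (3, cfg.feature_width) for f in feats)
    # the two kernel-32 stacks are distinct parameter sets
    assert not np.allclose(feats[0].data, feats[1].data)
    # ELU lower bound propagates through the stacks' activations
    h = ad.elu(ad.Tensor(rng.normal(size=(10, 10)) * 5))
    assert h.data.min() >= -1.0


def test_se_gates_in_unit_interval_and_zeroed_bottleneck_halves(rng):
    se = SqueezeExcite(5, ratio=4, rng=rng)
    groups = ad.Tensor(rng.normal(size=(6, 5, 16)))
    out = se(groups)
    gates = out.data / np.where(groups.data == 0, 1, groups.data)
    assert (gates > 0).all() and (gates < 1).all()
    for p in se.parameters():
        p.data[:] = 0.0
    halved = se(groups)
    assert np.allclose(halved.data, 0.5 * groups.data)


def test_combine_and_excite_dimension_is_sum_of_pairs(rng):
    se = SqueezeExcite(5, 4, rng)
    spec = SubbandFeatures(*[ad.Tensor(rng.normal(size=(4, 8))) for _ in range(5)])
    from seizdg.wavelet_frontend import TemporalFeatures

    temp = TemporalFeatures(*[ad.Tensor(rng.normal(size=(4, 8))) for _ in range(5)])
    out = combine_and_excite(spec, temp, se)
    assert out.shape == (4, 5 * 16)
    assert out.shape[1] % 2 == 0


def test_frontend_output_shape_is_deterministic(rng):
    cfg = _cfg()
    fe = Frontend(cfg, rng)
    out = fe(ad.Tensor(rng.uniform(size=(5, 3, 250))))
    assert out.shape == (5, cfg.feature_dim)
    assert cfg.feature_dim == 10 * cfg.feature_width
    assert np.isfinite(out.data).all()
    with pytest.raises(ValidationError):
        fe(ad.Tensor(rng.uniform(size=(5, 4, 250))))


def test_frontend_spectral_and_temporal_share_embedded_input(rng):
    """Both branches consume the same embedding-block output."""
    cfg = _cfg()
    fe = Frontend(cfg, rng)
    x = ad.Tensor(rng.uniform(size=(2, 3, 250)))
    embedded = fe.embedding(x)
    spec_out = fe.spectral(embedded)
    temp_out = fe.temporal(embedded)
    assert spec_out[0].shape == temp_out.members()[0].shape
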