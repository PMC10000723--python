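"""Conditional GAN core: networks, SSIM+BCE joint loss, augmentation, training.

The generator is a U-Net encoder-decoder with dropout in the decoder, mapping
a 2-channel (T1-w, non-fs T2-w) sagittal slice to a 1-channel synthetic
T2-w fs slice squashed to [-1, 1]. The discriminator is patch-based: it sees
the conditioning channels concatenated with a candidate T2-w fs slice and
emits a grid of per-patch real/synthetic scores.

The generator optimizes the joint loss

    L_G = (1 - SSIM(real, synthetic)) + lambda * BCE(1, D(synthetic)),

with lambda = 50 by default; the discriminator minimizes
BCE(1, D(real)) + BCE(0, D(synthetic)). Both networks train in turns with
Adam at learning rate 2e-4 for 25 epochs, visiting the training slices in a
freshly drawn random order every epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor
from .preprocess import PairedSliceDataset

# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SsimParams:
    """Windowed SSIM parameters for images on the [-1, 1] training range.

    ``c1 = (0.01 L)^2`` and ``c2 = (0.03 L)^2`` with dynamic range ``L = 2``
    are the standard stabilization constants. The window is uniform (11 x 11
    by default) and local statistics use the sample-covariance normalization
    ``n/(n-1)``, matching the common library convention.
    """

    window: int = 11
    data_range: float = 2.0
    k1: float = 0.01
    k2: float = 0.03

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("stabilization constants must be positive")


def ssim(a: np.ndarray, b: np.ndarray, params: SsimParams = SsimParams()) -> float:
    """Mean local SSIM between two equally shaped 2-D images.

    Symmetric in its arguments, 1.0 iff the images are identical, computed
    over all fully valid windows.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("images must be finite")
    if min(a.shape) < params.window:
        raise ValueError("image smaller than the SSIM window")
    win = params.window
    r = win // 2
    n = win * win
    cov_norm = n / (n - 1)

    def f(img):
        return ndimage.uniform_filter(img, win)[r:-r, r:-r]

    mu_a, mu_b = f(a), f(b)
    s_aa = cov_norm * (f(a * a) - mu_a * mu_a)
    s_bb = cov_norm * (f(b * b) - mu_b * mu_b)
    s_ab = cov_norm * (f(a * b) - mu_a * mu_b)
    c1, c2 = params.c1, params.c2
    s = ((2 * mu_a * mu_b + c1) * (2 * s_ab + c2)) / (
        (mu_a ** 2 + mu_b ** 2 + c1) * (s_aa + s_bb + c2))
    return float(s.mean())


def ssim_tensor(x: Tensor, y: Tensor, params: SsimParams = SsimParams()) -> Tensor:
    """Differentiable mean SSIM for (N, 1, H, W) tensors; same definition as
    :func:`ssim` so forward values agree to float precision."""
    win = params.window
    n = win * win
    cov_norm = n / (n - 1)
    mu_x = nn.box_mean(x, win)
    mu_y = nn.box_mean(y, win)
    s_xx = (nn.box_mean(x * x, win) - mu_x * mu_x) * cov_norm
    s_yy = (nn.box_mean(y * y, win) - mu_y * mu_y) * cov_norm
    s_xy = (nn.box_mean(x * y, win) - mu_x * mu_y) * cov_norm
    c1, c2 = params.c1, params.c2
    s = ((2.0 * mu_x * mu_y + c1) * (2.0 * s_xy + c2)) / (
        (mu_x * mu_x + mu_y * mu_y + c1) * (s_xx + s_yy + c2))
    return nn.mean_all(s)


# ---------------------------------------------------------------------------
# loss contracts (numpy surface; training uses the stable logit path)
# ---------------------------------------------------------------------------

def _check_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("discriminator scores must be finite")
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("discriminator scores must lie in [0, 1]")
    return scores


def generator_loss(real: np.ndarray, synthetic: np.ndarray, d_scores: np.ndarray,
                   lambda_adv: float = 50.0,
                   params: SsimParams = SsimParams()) -> float:
    """Joint generator loss: (1 - SSIM) plus lambda times the patch-averaged
    binary cross-entropy of the discriminator scores against all-ones.

    Boundary scores are handled exactly: a fully confident correct score
    contributes zero, a fully confident wrong score makes the BCE infinite.
    """
    scores = _check_scores(d_scores)
    if lambda_adv <= 0:
        raise ValueError("lambda_adv must be positive")
    with np.errstate(divide="ignore"):
        bce = float(np.mean(-np.log(scores)))
    return (1.0 - ssim(real, synthetic, params)) + lambda_adv * bce


def discriminator_loss(scores_real: np.ndarray, scores_synth: np.ndarray) -> float:
    """BCE(1, scores_real) + BCE(0, scores_synth), patch-averaged."""
    sr = _check_scores(scores_real)
    ss = _check_scores(scores_synth)
    with np.errstate(divide="ignore"):
        return float(np.mean(-np.log(sr)) + np.mean(-np.log(1.0 - ss)))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """Slice-level augmentation: spatial transforms hit inputs and target
    identically; intensity transforms hit the input channels only."""

    flip_prob: float = 0.5
    rotate_prob: float = 0.5
    max_rotation_deg: float = 10.0
    smooth_prob: float = 0.3
    smooth_sigma_range: tuple[float, float] = (0.2, 1.0)
    noise_prob: float = 0.3
    noise_sd_range: tuple[float, float] = (0.01, 0.05)

    def __post_init__(self) -> None:
        for p in (self.flip_prob, self.rotate_prob, self.smooth_prob, self.noise_prob):
            if not 0 <= p <= 1:
                raise ValueError("augmentation probabilities must lie in [0, 1]")
        if not 0 <= self.max_rotation_deg <= 45:
            raise ValueError("rotation range must lie within [0, 45] degrees")
        if self.smooth_sigma_range[0] < 0 or self.noise_sd_range[0] < 0:
            raise ValueError("sigma and noise ranges must be non-negative")


NO_AUGMENT = AugmentParams(flip_prob=0.0, rotate_prob=0.0, smooth_prob=0.0,
                           noise_prob=0.0)


def augment(record: tuple[np.ndarray, np.ndarray | None],
            params: AugmentParams = AugmentParams(),
            seed: int = 0) -> tuple[np.ndarray, np.ndarray | None]:
    """Augment one (inputs, target) slice record, deterministically per seed."""
    inputs, target = record
    inputs = np.asarray(inputs, dtype=np.float32).copy()
    target = None if target is None else np.asarray(target, dtype=np.float32).copy()
    rng = np.random.default_rng(seed)

    if rng.random() < params.flip_prob:
        inputs = inputs[..., ::-1].copy()
        if target is not None:
            target = target[..., ::-1].copy()
    if params.rotate_prob > 0 and rng.random() < params.rotate_prob:
        angle = float(rng.uniform(-params.max_rotation_deg, params.max_rotation_deg))
        if abs(angle) > params.max_rotation_deg:
            raise ValueError("rotation outside configured range")

        def rot(img):
            return ndimage.rotate(img, angle, axes=(-2, -1), reshape=False,
                                  order=1, mode="nearest")
        inputs = np.stack([rot(c) for c in inputs]).astype(np.float32)
        if target is not None:
            target = np.stack([rot(c) for c in target]).astype(np.float32)
    if rng.random() < params.smooth_prob:
        sigma = float(rng.uniform(*params.smooth_sigma_range))
        inputs = np.stack([ndimage.gaussian_filter(c, sigma) for c in inputs]
                          ).astype(np.float32)
    if rng.random() < params.noise_prob:
        sd = float(rng.uniform(*params.noise_sd_range))
        inputs = (inputs + rng.normal(0.0, sd, inputs.shape)).astype(np.float32)
    np.clip(inputs, -1.0, 1.0, out=inputs)
    if target is not None:
        np.clip(target, -1.0, 1.0, out=target)
    return inputs, target


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net shape: ``depth`` down/up levels, ``base_channels`` at the top,
    dropout in the (up to three) deepest decoder blocks."""

    depth: int = 3
    base_channels: int = 16
    dropout_rate: float = 0.5
    in_channels: int = 2
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Patch discriminator: ``n_blocks`` strided conv blocks over the
    concatenated (conditioning, candidate) channels."""

    n_blocks: int = 3
    base_channels: int = 16
    in_channels: int = 3

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.base_channels < 1:
            raise ValueError("n_blocks and base_channels must be >= 1")


class _Conv:
    def __init__(self, cin: int, cout: int, k: int, stride: int, padding: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, scale, (cout, cin, k, k)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return nn.conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class UNetGenerator:
    """Encoder-decoder with skip connections at every level.

    Output is tanh-squashed to [-1, 1] and spatially identical to the input;
    inputs must have spatial sides divisible by ``2**depth`` (see
    :func:`pad_to_multiple`). Dropout acts only when ``training=True``.
    """

    def __init__(self, spec: GeneratorSpec = GeneratorSpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        b = spec.base_channels
        self.enc0 = _Conv(spec.in_channels, b, 3, 1, 1, rng)
        self.downs = [_Conv(b * 2 ** (l - 1), b * 2 ** l, 3, 2, 1, rng)
                      for l in range(1, spec.depth + 1)]
        self.dec = []
        for l in range(spec.depth, 0, -1):
            cin = b * 2 ** l + b * 2 ** (l - 1)
            self.dec.append(_Conv(cin, b * 2 ** (l - 1), 3, 1, 1, rng))
        self.final = _Conv(b, spec.out_channels, 3, 1, 1, rng)
        # dropout in the deepest decoder blocks (pix2pix convention)
        n_drop = min(3, spec.depth)
        self.dropout_blocks = set(range(n_drop))

    @property
    def params(self) -> list[Tensor]:
        ps = self.enc0.params + self.final.params
        for c in self.downs + self.dec:
            ps += c.params
        return ps

    def forward(self, x: np.ndarray | Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        h, w = x.data.shape[2], x.data.shape[3]
        m = 2 ** self.spec.depth
        if h % m or w % m:
            raise ValueError(f"spatial size {(h, w)} not divisible by {m}; "
                             "use pad_to_multiple first")
        if training and self.spec.dropout_rate > 0 and rng is None:
            rng = np.random.default_rng(0)
        feats = [nn.leaky_relu(self.enc0(x))]
        for down in self.downs:
            feats.append(nn.leaky_relu(down(feats[-1])))
        hT = feats[-1]
        for i, dec in enumerate(self.dec):
            hT = nn.upsample2x(hT)
            hT = nn.concat_channels([hT, feats[-(i + 2)]])
            hT = nn.leaky_relu(dec(hT))
            if training and i in self.dropout_blocks and self.spec.dropout_rate > 0:
                hT = nn.dropout(hT, self.spec.dropout_rate, rng, training=True)
        return nn.tanh(self.final(hT))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic inference (dropout off)."""
        return self.forward(x, training=False).data

    # -- weights ------------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params
        if len(weights) != len(own):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = np.asarray(w, dtype=np.float32)


class PatchDiscriminator:
    """Strided conv stack emitting a grid of per-patch logits; sigmoid gives
    scores in (0, 1). Conditioning is channel concatenation of (T1, T2) with
    the candidate T2-fs slice."""

    def __init__(self, spec: DiscriminatorSpec = DiscriminatorSpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        b = spec.base_channels
        chans = [spec.in_channels] + [b * 2 ** i for i in range(spec.n_blocks)]
        self.blocks = [_Conv(chans[i], chans[i + 1], 4, 2, 1, rng)
                       for i in range(spec.n_blocks)]
        self.final = _Conv(chans[-1], 1, 3, 1, 1, rng)

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for c in self.blocks:
            ps += c.params
        return ps + self.final.params

    def logits(self, cond: Tensor, candidate: Tensor) -> Tensor:
        h = nn.concat_channels([cond, candidate])
        for blk in self.blocks:
            h = nn.leaky_relu(blk(h))
        return self.final(h)

    def scores(self, cond: np.ndarray, candidate: np.ndarray) -> np.ndarray:
        z = self.logits(Tensor(np.asarray(cond, dtype=np.float32)),
                        Tensor(np.asarray(candidate, dtype=np.float32)))
        return 1.0 / (1.0 + np.exp(-z.data))


def pad_to_multiple(x: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad the two trailing axes up to the next multiple; returns the
    padded array and the original (H, W) for cropping back."""
    h, w = x.shape[-2], x.shape[-1]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return x, (h, w)
    pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(x, pad, mode="reflect"), (h, w)


def crop_to(x: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    return x[..., :hw[0], :hw[1]]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Desk-scale training configuration.

    ``lambda_adv`` weights the adversarial BCE term against (1 - SSIM) in
    the generator loss; learning rate, epoch count and the Adam betas follow
    the conditional-GAN convention. All randomness (init, epoch shuffling,
    dropout, augmentation) flows from ``seed``.
    """

    lambda_adv: float = 50.0
    learning_rate: float = 2e-4
    epochs: int = 25
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 8
    seed: int = 0
    augment: AugmentParams | None = field(default_factory=AugmentParams)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    ssim: SsimParams = field(default_factory=SsimParams)

    def __post_init__(self) -> None:
        if self.lambda_adv <= 0:
            raise ValueError("lambda_adv must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def train(dataset: PairedSliceDataset, config: TrainConfig = TrainConfig(),
          ) -> tuple[dict, list[dict]]:
    """Alternating discriminator/generator training.

    Returns a serializable checkpoint dict (see :func:`save_checkpoint`) and
    a per-epoch loss history whose reported generator loss is exactly the sum
    of its logged (1 - SSIM) and lambda*BCE components.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if not dataset.has_targets:
        raise ValueError("training requires target T2-fs slices")
    master = np.random.default_rng(config.seed)
    gen = UNetGenerator(config.generator, seed=int(master.integers(2 ** 31)))
    disc = PatchDiscriminator(config.discriminator, seed=int(master.integers(2 ** 31)))
    opt_g = nn.Adam(gen.params, lr=config.learning_rate, betas=config.betas)
    opt_d = nn.Adam(disc.params, lr=config.learning_rate, betas=config.betas)
    shuffle_rng = np.random.default_rng(int(master.integers(2 ** 31)))
    aug_rng = np.random.default_rng(int(master.integers(2 ** 31)))
    drop_rng = np.random.default_rng(int(master.integers(2 ** 31)))

    n = len(dataset)
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        ssim_sum = adv_sum = d_sum = 0.0
        n_batches = 0
        g_updates = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xs, ys = [], []
            for i in idx:
                xi, yi = dataset.inputs[i], dataset.targets[i]
                if config.augment is not None:
                    xi, yi = augment((xi, yi), config.augment,
                                     seed=int(aug_rng.integers(2 ** 31)))
                xs.append(xi)
                ys.append(yi)
            x = np.stack(xs).astype(np.float32)
            y_real = np.stack(ys).astype(np.float32)
            xt = Tensor(x)
            yt = Tensor(y_real)

            # generator forward (dropout active)
            y_syn = gen.forward(xt, training=True, rng=drop_rng)

            # --- discriminator step (synthetic detached) --------------------
            opt_d.zero_grad()
            z_real = disc.logits(xt, yt)
            z_fake = disc.logits(xt, Tensor(y_syn.data.copy()))
            loss_d = nn.mean_all(nn.softplus(-z_real)) + nn.mean_all(nn.softplus(z_fake))
            loss_d.backward()
            opt_d.step()

            # --- generator step --------------------------------------------
            opt_g.zero_grad()
            for p in disc.params:
                p.grad = None
            z_syn = disc.logits(xt, y_syn)
            adv = nn.mean_all(nn.softplus(-z_syn))
            ssim_val = ssim_tensor(yt, y_syn, config.ssim)
            loss_g = (1.0 - ssim_val) + config.lambda_adv * adv
            loss_g.backward()
            for p in disc.params:       # D only judges during the G step
                p.grad = None
            opt_g.step()
            g_updates += 1

            lv_d, lv_s, lv_a = loss_d.item(), 1.0 - ssim_val.item(), \
                config.lambda_adv * adv.item()
            if not (np.isfinite(lv_d) and np.isfinite(lv_s) and np.isfinite(lv_a)):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch + 1}, "
                    f"batch {n_batches + 1}: d={lv_d} ssim_term={lv_s} adv={lv_a}")
            ssim_sum += lv_s
            adv_sum += lv_a
            d_sum += lv_d
            n_batches += 1
        g_ssim_term = ssim_sum / n_batches
        g_adv_term = adv_sum / n_batches
        history.append({
            "epoch": epoch + 1,
            "g_loss": g_ssim_term + g_adv_term,
            "g_ssim_term": g_ssim_term,
            "g_adv_term": g_adv_term,
            "d_loss": d_sum / n_batches,
            "n_g_updates": g_updates,
        })
    checkpoint = {
        "generator_spec": asdict(config.generator),
        "generator_weights": gen.get_weights(),
        "config": _config_to_dict(config),
        "seed": config.seed,
    }
    return checkpoint, history


def _config_to_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    return d


def make_generator_from_checkpoint(checkpoint: dict) -> UNetGenerator:
    spec = GeneratorSpec(**checkpoint["generator_spec"])
    gen = UNetGenerator(spec, seed=0)
    gen.set_weights(checkpoint["generator_weights"])
    return gen


def save_checkpoint(checkpoint: dict, path: str | Path) -> None:
    """Self-describing archive: weights as npz members plus a JSON header."""
    path = Path(path)
    meta = {k: v for k, v in checkpoint.items() if k != "generator_weights"}
    arrays = {f"w{i}": w for i, w in enumerate(checkpoint["generator_weights"])}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, default=_json_default).encode(), dtype=np.uint8), **arrays)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_checkpoint(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        weights = [z[f"w{i}"] for i in range(sum(1 for k in z.files
                                                 if k.startswith("w")))]
    meta["generator_weights"] = weights
    return meta


def save_history_csv(history: list[dict], path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame(history).to_csv(path, index=False)
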