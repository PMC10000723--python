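"""Slice-wise application of a trained generator to whole volumes."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gan_core import (SsimParams, UNetGenerator, crop_to, load_checkpoint,
                       make_generator_from_checkpoint, pad_to_multiple, ssim)
from .volumes import ContrastVolume


@dataclass
class SynthesisResult:
    """Synthetic T2-w fs volume plus an optional per-slice quality surface."""

    volume: ContrastVolume
    per_slice_ssim: list[float] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def mean_ssim(self) -> float | None:
        if self.per_slice_ssim is None:
            return None
        return float(np.mean(self.per_slice_ssim))


def _resolve_generator(checkpoint) -> tuple[UNetGenerator, dict]:
    if isinstance(checkpoint, UNetGenerator):
        return checkpoint, {"checkpoint": "in-memory generator"}
    if isinstance(checkpoint, (str, Path)):
        ck = load_checkpoint(checkpoint)
        return make_generator_from_checkpoint(ck), {"checkpoint": str(checkpoint),
                                                    "seed": ck.get("seed")}
    if isinstance(checkpoint, dict):
        return make_generator_from_checkpoint(checkpoint), {
            "checkpoint": "in-memory dict", "seed": checkpoint.get("seed")}
    raise TypeError("checkpoint must be a path, checkpoint dict or UNetGenerator")


def synthesize_volume(t1: ContrastVolume, t2: ContrastVolume, checkpoint,
                      reference: ContrastVolume | None = None,
                      stochastic: bool = False, seed: int = 0,
                      ssim_params: SsimParams = SsimParams()) -> SynthesisResult:
    """Pass every sagittal slice of a preprocessed (T1, T2) pair through the
    generator and restack the outputs into a synthetic T2-w fs volume.

    Inputs must be co-registered, equally shaped, and scaled to [-1, 1].
    Inference is deterministic (dropout off) unless ``stochastic=True``, in
    which case decoder dropout stays active and is seeded by ``seed``.
    When ``reference`` (a real T2-w fs) is supplied, per-slice SSIM against
    it is recorded.
    """
    if t1.slices().shape != t2.slices().shape:
        raise ValueError("T1 and T2 volumes must share a shape")
    if reference is not None and reference.slices().shape != t1.slices().shape:
        raise ValueError("reference volume shape mismatch")
    gen, provenance = _resolve_generator(checkpoint)

    x = np.stack([t1.slices(), t2.slices()], axis=1).astype(np.float32)
    x_pad, hw = pad_to_multiple(x, 2 ** gen.spec.depth)
    if stochastic:
        rng = np.random.default_rng(seed)
        y = gen.forward(x_pad, training=True, rng=rng).data
    else:
        y = gen.predict(x_pad)
    y = crop_to(y, hw)[:, 0]
    y = np.clip(y, -1.0, 1.0)

    data = np.moveaxis(y, 0, t2.slice_axis)
    vol = ContrastVolume(data=data, spacing=t2.spacing, contrast="SYNTH_T2FS",
                         slice_axis=t2.slice_axis, meta=dict(t2.meta))
    per_slice = None
    if reference is not None:
        per_slice = [ssim(y[k], reference.slices()[k], ssim_params)
                     for k in range(y.shape[0])]
    provenance["stochastic"] = stochastic
    return SynthesisResult(volume=vol, per_slice_ssim=per_slice,
                           provenance=provenance)


def evaluate_synthesis(result: SynthesisResult, reference: ContrastVolume,
                       ssim_params: SsimParams = SsimParams(),
                       ) -> tuple[list[float], float]:
    """Per-slice SSIM of the synthetic volume against a reference, and the
    volume mean (arithmetic mean of the per-slice values)."""
    syn = result.volume.slices()
    ref = reference.slices()
    if syn.shape != ref.shape:
        raise ValueError("reference volume shape mismatch")
    per_slice = [ssim(syn[k], ref[k], ssim_params) for k in range(syn.shape[0])]
    return per_slice, float(np.mean(per_slice))
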