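"""Grad-CAM for 1-D onset predictions.

For a chosen head (inspiratory or expiratory) and a chosen timestep of the
output span, the gradient of the pre-sigmoid logit is taken with respect to
the last convolutional feature map of the shared U-Net trunk (the final
decoder convolution, before center cropping).  Channel weights are the
time-averaged gradients; the heatmap is the rectified weighted sum of the
feature maps, linearly interpolated to the input length and normalized to a
maximum of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError
from .unet import UNet1d

__all__ = ["CamResult", "grad_cam"]


@dataclass
class CamResult:
    heat: np.ndarray  # per-input-timestep importance in [0, 1], length input_len
    target_head: str  # 'insp' | 'exp'
    target_timestep: int  # index within the output span
    predicted_probability: float


def grad_cam(model: UNet1d, window: np.ndarray, head: str = "insp", timestep: int = 0) -> CamResult:
    """Compute a Grad-CAM heatmap for one normalized input window.

    ``window`` is (input_len, 2); ``timestep`` indexes the output span
    (``[0, output_len)``).  Inference is deterministic (no dropout), so two
    calls with identical inputs yield identical heat.
    """
    c = model.config
    if not (0 <= timestep < c.output_len):
        raise ConfigurationError(f"timestep must lie in [0, {c.output_len})")
    if head not in ("insp", "exp"):
        raise ConfigurationError("head must be 'insp' or 'exp'")
    window = np.asarray(window, dtype=np.float32)
    if window.shape != (c.input_len, c.channels_in):
        raise ConfigurationError(f"window must have shape ({c.input_len}, {c.channels_in})")

    out = model.forward(window[None], training=False, return_internals=True)
    logit = out[f"logit_{head}"][0, timestep, 0]
    logit.backward()
    trunk = out["trunk"]
    feats = trunk.data[0]  # (L_trunk, C)
    grads = trunk.grad[0] if trunk.grad is not None else np.zeros_like(feats)

    weights = grads.mean(axis=0)  # time-averaged gradient per channel
    cam = np.maximum(feats @ weights, 0.0)
    if cam.max() <= 0 or not np.any(grads):
        if not np.any(grads):
            warnings.warn("all-zero gradients: returning flat zero heat", stacklevel=2)
        heat = np.zeros(c.input_len)
    else:
        if len(cam) != c.input_len:
            positions = np.linspace(0, c.input_len - 1, num=len(cam))
            cam = np.interp(np.arange(c.input_len), positions, cam)
        heat = cam / cam.max()

    prob = float(out[f"p_{head}"].data[0, timestep, 0])
    return CamResult(
        heat=heat, target_head=head, target_timestep=int(timestep), predicted_probability=prob
    )
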