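"""Grad-CAM saliency for 1-D spectral regression.

For a regression network the "class" score is the scalar firmness output:
channel weights are the spatial average of its gradient with respect to the
feature maps of a chosen convolutional layer; the saliency map is the
channel-weighted sum of those feature maps, linearly upsampled to the input
length and min-max normalized to [0, 1].

Two choices differ from the classification-style recipe, both because the
"class" here is a signed regression output:

* weighting: the classic form averages each channel's gradient over
  position and multiplies the whole feature map by that scalar, which on a
  shallow 1-D network smears evidence into a near-uniform pedestal.  The
  default here multiplies gradients and activations position-by-position
  before summing channels (the first-order contribution of each position,
  as in HiResCAM); ``weighting='average'`` restores the classic form.
* sign: classification Grad-CAM rectifies the map, keeping only evidence
  *for* the class.  For regression, a region that pulls the prediction
  down for a soft fruit is exactly as relevant as one that pushes it up
  for a firm one, so the default takes the absolute contribution
  (``mode='abs'``); ``mode='relu'`` keeps the one-sided convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isnet1d import Conv1d, ISNetError, Network, TrainedNet

__all__ = ["InterpretError", "SaliencyMap", "grad_cam_1d", "band_saliency"]


class InterpretError(ValueError):
    """Domain error raised by the interpretation stage."""


@dataclass(frozen=True)
class SaliencyMap:
    """Min-max-normalized saliency over the input frequency bins."""

    values: np.ndarray
    source_id: str = ""
    layer: str = "final_conv"
    degenerate: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise InterpretError("saliency values must lie in [0, 1]")


def grad_cam_1d(
    net: TrainedNet | Network,
    spectrum: np.ndarray,
    layer: str = "final_conv",
    source_id: str = "",
    mode: str = "abs",
    weighting: str = "positional",
) -> SaliencyMap:
    """Grad-CAM map for one standardized spectrum.

    ``layer`` must name a convolutional layer; the default is the last
    convolution of the main path.  ``mode='abs'`` (default) keeps the
    magnitude of the signed regression evidence, ``mode='relu'`` the
    one-sided classification convention.  ``weighting='positional'``
    (default) multiplies gradients and activations per position before
    summing channels; ``weighting='average'`` uses the classic
    spatially-averaged channel weights.  A constant map is returned as
    zeros with the ``degenerate`` flag set.
    """
    network = net.network if isinstance(net, TrainedNet) else net
    target = network.layer(layer)
    if not isinstance(target, Conv1d):
        raise InterpretError(f"layer {layer!r} is not convolutional")

    x = np.atleast_2d(np.asarray(spectrum, dtype=np.float64))
    if x.shape[0] != 1:
        raise InterpretError("grad_cam_1d expects a single spectrum")

    capture: dict[str, np.ndarray] = {}
    network.forward(x, train=False, dtype=np.float64, capture=capture)
    A = capture[layer][0]                                   # (C, L')
    network.zero_grads()
    g = network.backward(np.ones((1, 1)), to_layer=layer)[0]  # dy/dA, (C, L')
    network.zero_grads()

    if weighting == "positional":
        weighted = (g * A).sum(axis=0)                      # (L',)
    elif weighting == "average":
        weighted = g.mean(axis=1) @ A
    else:
        raise InterpretError(f"unknown weighting {weighting!r}")
    if mode == "abs":
        cam = np.abs(weighted)
    elif mode == "relu":
        cam = np.maximum(weighted, 0.0)
    else:
        raise InterpretError(f"unknown mode {mode!r}")

    n_in = network.input_length
    pos = np.linspace(0, len(cam) - 1, n_in)
    cam_up = np.interp(pos, np.arange(len(cam)), cam)

    lo, hi = float(cam_up.min()), float(cam_up.max())
    if hi - lo <= 0.0:
        return SaliencyMap(values=np.zeros(n_in), source_id=source_id,
                           layer=layer, degenerate=True)
    values = (cam_up - lo) / (hi - lo)
    return SaliencyMap(values=values, source_id=source_id, layer=layer)


def band_saliency(
    saliency: SaliencyMap,
    band: tuple[float, float],
    grid: np.ndarray,
) -> float:
    """Mean saliency over frequencies in the half-open band [lo, hi)."""
    lo, hi = band
    grid = np.asarray(grid, dtype=float)
    if len(grid) != len(saliency.values):
        raise InterpretError("grid length must match the saliency map")
    mask = (grid >= lo) & (grid < hi)
    if not mask.any():
        raise InterpretError(f"band [{lo}, {hi}) contains no grid points")
    return float(np.mean(saliency.values[mask]))
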