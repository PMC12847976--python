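"""Background removal for chip fluorescence images.

The rolling-ball algorithm estimates the background as the surface traced by
a ball of given radius rolled under the intensity landscape; structures
narrower than the ball (vessels) are left intact while slowly varying
illumination is removed. For large radii the background is estimated on a
downscaled copy (as the classic ImageJ implementation does) — the estimate
is smooth, so the approximation error is small and the speedup is ~radius².
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball as _rolling_ball
from skimage.transform import resize

from .types import ChipImage, ParameterError

#: background is estimated at 1/DOWNSCALE resolution for radii >= this
_DOWNSCALE_RADIUS = 16
_DOWNSCALE = 4


def estimate_background(
    data: np.ndarray,
    radius: float,
    smooth_sigma: float = 0.0,
    downscale: Optional[bool] = None,
) -> np.ndarray:
    """Rolling-ball background estimate of a 2-D intensity array."""
    if radius < 1:
        raise ParameterError("rolling-ball radius must be >= 1")
    if radius >= max(data.shape):
        raise ParameterError(
            f"radius {radius} exceeds both image dimensions {data.shape}"
        )
    img = np.asarray(data, dtype=np.float64)
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    if downscale is None:
        downscale = radius >= _DOWNSCALE_RADIUS
    if downscale:
        small = ndimage.zoom(img, 1.0 / _DOWNSCALE, order=1, grid_mode=True, mode="nearest")
        bg_small = _rolling_ball(small, radius=radius / _DOWNSCALE)
        bg = resize(bg_small, img.shape, order=1, mode="edge", anti_aliasing=False)
        # a background estimate must stay below the image it explains
        bg = np.minimum(bg, np.asarray(data, dtype=np.float64))
    else:
        bg = _rolling_ball(img, radius=radius)
    return bg


def rolling_ball_subtract(
    image: ChipImage,
    radius: float = 50.0,
    smooth_sigma: float = 0.0,
    downscale: Optional[bool] = None,
) -> ChipImage:
    """Subtract the rolling-ball background; output clipped to be >= 0.

    Parameters
    ----------
    image
        Input chip image.
    radius
        Ball radius in pixels; should exceed the widest vessel by >2x.
    smooth_sigma
        Optional Gaussian smoothing applied only to the background estimate
        input (off by default).
    downscale
        Force (True) or forbid (False) the downscaled estimate; by default
        it is used for radii >= 16 px.
    """
    bg = estimate_background(image.data, radius, smooth_sigma, downscale)
    out = np.clip(np.asarray(image.data, dtype=np.float64) - bg, 0.0, None)
    return image.with_data(out)
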