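"""Render a :class:`~mugr.simulate.TissueModel` as a multi-channel section.

Channels (float32, arbitrary intensity units on [0, ~1]):

* ``dapi``  — every nucleus as an 8 µm disk;
* ``hu``    — neuron nuclei only;
* ``s100b`` — glial nuclei, ganglion neuropil (glial cytoplasm around the
  neuron chain, with non-glial nuclei left dark) and nerve bundles.

The circular muscle band occupies the lower part of the frame with V-shaped
notches cut into its outer (myenteric-facing) edge at junctions and shallow
depressions. Truth label masks are exactly consistent with the model.
Image x is the longitudinal axis; pixel (0, 0) is the proximal/oral top-left
corner; calibration is isotropic µm-per-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .errors import ResolutionError
from .params import SimulationParams
from .simulate import (
    JUNCTION_NOTCH_SLOPE,
    MUSCLE_THICKNESS,
    MUSCLE_TOP,
    SECTION_HEIGHT,
    SHALLOW_NOTCH_SLOPE,
    TissueModel,
)

__all__ = ["RenderedSection", "render_section"]

CHANNELS = ("dapi", "hu", "s100b")

_NEUROPIL_INTENSITY = 0.45
_BUNDLE_INTENSITY = 0.9
_NUCLEUS_INTENSITY = 1.0


@dataclass
class RenderedSection:
    channels: dict[str, np.ndarray]  # name -> (H, W) float32
    um_per_px: float
    nuclei_labels: np.ndarray  # uint16, 1-based ids matching truth_table rows
    muscle_mask: np.ndarray  # bool
    s100b_labels: np.ndarray  # uint16 structure labels (bundles then ganglia)
    truth_table: pd.DataFrame  # nuclei records (id, x, y, class, ganglion_id)
    model: TissueModel = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.muscle_mask.shape

    def stack(self) -> np.ndarray:
        return np.stack([self.channels[c] for c in CHANNELS])


def _disk(img: np.ndarray, x_um: float, y_um: float, r_um: float, upp: float,
          value: float) -> None:
    rr, cc = draw_disk((y_um / upp, x_um / upp), max(r_um / upp, 1.0),
                       shape=img.shape)
    img[rr, cc] = np.maximum(img[rr, cc], value)


def render_section(
    model: TissueModel,
    params: SimulationParams | None = None,
    rng: np.random.Generator | None = None,
) -> RenderedSection:
    """Rasterise one section; deterministic given the model's seed."""
    params = params or model.params
    upp = params.um_per_px
    if upp > 10.0:
        raise ResolutionError(
            f"um_per_px={upp}: a 30 µm junction valley would span fewer than "
            "3 pixels"
        )
    if rng is None:
        rng = np.random.default_rng([params.seed, 17])

    W = int(np.ceil(model.axis_length / upp))
    H = int(np.ceil(SECTION_HEIGHT / upp))
    x_um = (np.arange(W) + 0.5) * upp
    y_um = (np.arange(H) + 0.5) * upp

    # ---- circular muscle band with notched outer edge ----------------------
    notch = np.zeros(W)
    for x, d in zip(model.unit_edges[1:-1], model.junction_depths):
        notch = np.maximum(notch, d - JUNCTION_NOTCH_SLOPE * np.abs(x_um - x))
    for x, d in model.shallow:
        notch = np.maximum(notch, d - SHALLOW_NOTCH_SLOPE * np.abs(x_um - x))
    notch = np.clip(notch, 0.0, None)
    t = y_um[:, None] - MUSCLE_TOP  # depth below the nominal outer edge
    muscle_mask = (t >= notch[None, :]) & (t < MUSCLE_THICKNESS)

    dapi = np.zeros((H, W), dtype=np.float32)
    hu = np.zeros((H, W), dtype=np.float32)
    s100b = np.zeros((H, W), dtype=np.float32)
    nuclei_labels = np.zeros((H, W), dtype=np.uint16)
    s100b_labels = np.zeros((H, W), dtype=np.uint16)

    r_nuc = model.params.nucleus_diameter / 2

    # ---- S100B structures: bundles, then ganglion neuropil -----------------
    sid = 0
    for b in model.bundles:
        sid += 1
        rr, cc = draw_ellipse(
            b.center_y / upp, b.center_x / upp,
            max(b.width / 2 / upp, 1.0), max(b.length / 2 / upp, 1.0),
            shape=(H, W),
        )
        s100b[rr, cc] = np.maximum(s100b[rr, cc], _BUNDLE_INTENSITY)
        s100b_labels[rr, cc] = sid
    for g in model.ganglia:
        sid += 1
        anchors = g.nuclei_xy[g.classes == "neuron"]
        for ax, ay in anchors:
            rr, cc = draw_disk((ay / upp, ax / upp), 22.0 / upp, shape=(H, W))
            s100b[rr, cc] = np.maximum(s100b[rr, cc], _NEUROPIL_INTENSITY)
            s100b_labels[rr, cc] = sid
    # non-glial nuclei are S100B-dark: punch holes before adding glia
    for g in model.ganglia:
        for (nx, ny), cls in zip(g.nuclei_xy, g.classes):
            if cls != "glia":
                rr, cc = draw_disk((ny / upp, nx / upp), (r_nuc + 1) / upp,
                                   shape=(H, W))
                s100b[rr, cc] = 0.0

    # ---- nuclei -------------------------------------------------------------
    truth_rows = []
    nid = 0
    for gid, g in enumerate(model.ganglia):
        for (nx, ny), cls in zip(g.nuclei_xy, g.classes):
            nid += 1
            rr, cc = draw_disk((ny / upp, nx / upp), r_nuc / upp, shape=(H, W))
            dapi[rr, cc] = _NUCLEUS_INTENSITY
            nuclei_labels[rr, cc] = nid
            if cls == "neuron":
                hu[rr, cc] = _NUCLEUS_INTENSITY
            elif cls == "glia":
                s100b[rr, cc] = _NUCLEUS_INTENSITY
            truth_rows.append((nid, float(nx), float(ny), str(cls), gid))
    for (nx, ny) in model.isolated_glia:
        nid += 1
        rr, cc = draw_disk((ny / upp, nx / upp), r_nuc / upp, shape=(H, W))
        dapi[rr, cc] = _NUCLEUS_INTENSITY
        nuclei_labels[rr, cc] = nid
        s100b[rr, cc] = _NUCLEUS_INTENSITY
        truth_rows.append((nid, float(nx), float(ny), "glia", -1))

    # ---- soften + noise -----------------------------------------------------
    sigma_px = 1.0
    channels = {}
    for name, img in (("dapi", dapi), ("hu", hu), ("s100b", s100b)):
        img = ndimage.gaussian_filter(img, sigma_px)
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, img.shape)
        channels[name] = np.clip(img, 0.0, None).astype(np.float32)

    truth_table = pd.DataFrame(
        truth_rows, columns=["id", "x_um", "y_um", "cell_class", "ganglion_id"]
    )
    return RenderedSection(
        channels=channels,
        um_per_px=upp,
        nuclei_labels=nuclei_labels,
        muscle_mask=muscle_mask,
        s100b_labels=s100b_labels,
        truth_table=truth_table,
        model=model,
    )
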