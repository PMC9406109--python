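"""Parameter models: simulation conditions, segmentation knobs and scoring thresholds.

All length-valued parameters are in micrometres (µm). Defaults encode the
study conditions of the underlying quantitative-histology protocol: circular
muscle units of width 249 ± 62 µm separated by junction valleys at least
30 µm deep, myenteric ganglia of roughly 24 nuclei of which ~30% are
HuC/D+ neurons, and hypertrophic S100B+ nerve bundles wider than 40 µm
marking the start of the transition zone.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import SizingError

ZoneLabel = Literal["normal", "transition", "aganglionic"]

#: Minimum valley depth (µm) that qualifies as a muscle-unit junction.
JUNCTION_DEPTH_CRITERION = 30.0


class SimulationParams(BaseModel):
    """Conditions for one synthetic longitudinal strip of circular muscle.

    ``zone_layout`` assigns consecutive muscle units to zones; the spans of
    the zones are therefore tiled by whole units and cover the strip without
    overlap. Ganglion placement is Bernoulli per unit with a zone-specific
    probability, so the expected number of muscle units between adjacent
    ganglia is 1/p (geometric interval counts).
    """

    model_config = ConfigDict(frozen=True)

    n_units: int = Field(default=60, ge=1)
    unit_width_mean: float = Field(default=249.0, gt=0)
    unit_width_sd: float = Field(default=62.0, ge=0)
    unit_width_floor: float = Field(default=80.0, gt=0)

    junction_depth_mean: float = Field(default=42.0, gt=0)
    junction_depth_sd: float = Field(default=6.0, ge=0)
    junction_depth_floor: float = Field(default=33.0, gt=0)

    shallow_depression_rate: float = Field(default=0.3, ge=0, le=1)
    shallow_depression_depth_min: float = Field(default=5.0, gt=0)
    shallow_depression_depth_max: float = Field(default=25.0, gt=0)

    p_ganglion_normal: float = Field(default=0.78, ge=0, le=1)
    p_ganglion_tz: float = Field(default=0.52, ge=0, le=1)

    ganglion_ncells_mean: float = Field(default=24.0, gt=0)
    neuron_fraction: float = Field(default=0.30, gt=0, le=1)
    glia_per_neuron: float = Field(default=2.8, ge=0)
    nucleus_diameter: float = Field(default=8.0, gt=0)

    bundle_width_range: tuple[float, float] = (45.0, 80.0)
    bundle_length: float = Field(default=100.0, gt=0)
    n_bundles_tz: int = Field(default=3, ge=1)

    zone_layout: tuple[tuple[ZoneLabel, int], ...] = (
        ("normal", 30),
        ("transition", 20),
        ("aganglionic", 10),
    )

    isolated_glia_per_unit: float = Field(default=0.15, ge=0)
    noise_sd: float = Field(default=0.05, ge=0)
    um_per_px: float = Field(default=1.0, gt=0)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationParams":
        if self.shallow_depression_depth_max >= JUNCTION_DEPTH_CRITERION:
            raise ValueError(
                "shallow_depression_depth_max must stay below the 30 µm "
                "junction criterion"
            )
        if self.shallow_depression_depth_min >= self.shallow_depression_depth_max:
            raise ValueError("shallow depression depth range is empty")
        if self.junction_depth_floor < JUNCTION_DEPTH_CRITERION:
            raise ValueError(
                "junction_depth_floor below 30 µm would generate borders that "
                "are not junctions by definition"
            )
        lo, hi = self.bundle_width_range
        if not (0 < lo <= hi):
            raise ValueError("bundle_width_range must be a positive (lo, hi) pair")
        labels = [z for z, _ in self.zone_layout]
        if len(labels) != len(set(labels)):
            raise ValueError("zone labels must be unique in zone_layout")
        if any(n < 0 for _, n in self.zone_layout):
            raise ValueError("zone unit counts must be non-negative")
        total = sum(n for _, n in self.zone_layout)
        if total != self.n_units:
            raise SizingError(
                f"zone layout covers {total} units but n_units={self.n_units}; "
                "zones must tile the strip exactly"
            )
        return self

    # ---- derived, self-consistent cell-class probabilities ----------------
    @property
    def class_probs(self) -> tuple[float, float, float]:
        """(neuron, glia, other) probabilities for ganglion nuclei.

        Neuron probability is ``neuron_fraction``. The glia probability is
        ``glia_per_neuron * neuron_fraction`` capped so that a small
        unlabelled ("other") remainder always exists: nuclei immunoreactive
        for neither marker are a real feature of ganglia and probabilities
        must sum to one.
        """
        p_n = self.neuron_fraction
        min_other = 0.02 if p_n < 0.98 else 0.0
        p_g = min(self.glia_per_neuron * p_n, max(0.0, 1.0 - p_n - min_other))
        p_o = max(0.0, 1.0 - p_n - p_g)
        return (p_n, p_g, p_o)

    @property
    def effective_glia_per_neuron(self) -> float:
        """Glia:neuron ratio the generator actually realises in expectation."""
        p_n, p_g, _ = self.class_probs
        return p_g / p_n


class Thresholds(BaseModel):
    """Operational scoring definitions (all lengths in µm)."""

    model_config = ConfigDict(frozen=True)

    junction_min_depth: float = Field(default=30.0, gt=0)
    width_offset: float = Field(default=50.0, gt=0)
    bundle_hypertrophy_width: float = Field(default=40.0, gt=0)
    #: strict ``>`` comparison by default; inclusive ``>=`` available.
    bundle_width_inclusive: bool = False
    min_neurons_per_ganglion: int = Field(default=2, ge=1)
    ganglion_link_distance: float = Field(default=30.0, gt=0)
    n_sections_required: int = Field(default=3, ge=1)


class NucleusDetectionParams(BaseModel):
    """Blob detection settings for DAPI+ nuclei."""

    model_config = ConfigDict(frozen=True)

    intensity_threshold: float = Field(default=0.5, gt=0)
    blob_sigma_um: float = Field(default=2.8, gt=0)
    blob_threshold: float = Field(default=0.05, gt=0)
    min_area_um2: float = Field(default=15.0, gt=0)
    max_area_um2: float = Field(default=250.0, gt=0)


class CellClassParams(BaseModel):
    """Marker-positivity settings for Hu/S100B classification."""

    model_config = ConfigDict(frozen=True)

    k_hu: float = Field(default=2.0, gt=0)
    k_s100b: float = Field(default=2.0, gt=0)
    #: lower bound for the background estimate, in intensity units; keeps the
    #: fold-over-background test meaningful on near-zero-background images.
    background_floor: float = Field(default=0.125, gt=0)
    measure_radius_um: float = Field(default=2.0, gt=0)


class ComponentParams(BaseModel):
    """Connected-component extraction settings for the S100B channel."""

    model_config = ConfigDict(frozen=True)

    intensity_threshold: float = Field(default=0.25, gt=0)
    min_area_um2: float = Field(default=120.0, gt=0)


class SegmentationParams(BaseModel):
    """Bundle of all segmentation-stage settings."""

    model_config = ConfigDict(frozen=True)

    nuclei: NucleusDetectionParams = NucleusDetectionParams()
    classify: CellClassParams = CellClassParams()
    components: ComponentParams = ComponentParams()
    profile_window_um: float = Field(default=400.0, gt=0)
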